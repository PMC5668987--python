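"""Per-gene replication timing, TAD entropy, and timing-vs-bias regressions.

Replication timing per gene is the basepair-weighted average of segment
signals over the gene body::

    R_gene = sum_i(R_i * bpOverlap_i) / totalBpInGene

where ``totalBpInGene`` is the full gene length; basepairs not covered by
any segment contribute zero to the numerator (a covered-bp-only
normalization is available). TAD entropy measures spatial clustering of
sex-biased genes: for TAD ``i`` with proportion ``p_i`` of sex-biased
genes, entropy is ``-p_i * ln(p_i)`` (single-term as used for this
statistic, natural log; the standard binary entropy is behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io import require_columns


class TrackError(ValueError):
    """A genomic track violates its invariants (e.g. overlapping segments)."""


def _check_disjoint(track: pd.DataFrame, what: str) -> None:
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise TrackError(f"{what} has overlapping intervals on {chrom}")


def replication_timing_per_gene(genes: pd.DataFrame,
                                segments: pd.DataFrame,
                                normalize_covered: bool = False) -> pd.Series:
    """Basepair-weighted average replication signal per gene.

    ``segments`` must be non-overlapping within the track (error otherwise).
    Genes with zero covered basepairs get NaN. With ``normalize_covered``
    the denominator is the covered length instead of the full gene length.
    """
    require_columns(genes, ["gene_id", "chrom", "start", "end"], "annotation")
    require_columns(segments, ["chrom", "start", "end", "value"], "replication track")
    _check_disjoint(segments, "replication track")
    by_chrom = {
        chrom: sub.sort_values("start")[["start", "end", "value"]].to_numpy(dtype=float)
        for chrom, sub in segments.groupby("chrom")
    }
    values = np.full(len(genes), np.nan)
    for i, (gene_start, gene_end, chrom) in enumerate(
            zip(genes["start"], genes["end"], genes["chrom"])):
        gene_start, gene_end = int(gene_start), int(gene_end)
        if gene_end <= gene_start:
            raise TrackError(f"gene {genes['gene_id'].iloc[i]!r} has non-positive length")
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        overlap = np.minimum(arr[:, 1], gene_end) - np.maximum(arr[:, 0], gene_start)
        overlap = np.clip(overlap, 0, None)
        covered = overlap.sum()
        if covered == 0:
            continue
        numerator = float(np.dot(arr[:, 2], overlap))
        denom = covered if normalize_covered else (gene_end - gene_start)
        values[i] = numerator / denom
    return pd.Series(values, index=genes["gene_id"].to_numpy(), name="rep_timing")


def single_term_entropy(p: float | np.ndarray, binary: bool = False) -> float | np.ndarray:
    """``-p * ln(p)`` with the continuity convention entropy(0) = 0.

    The single-term form is zero at both p=0 and p=1 and peaks at 1/e when
    p = 1/e. With ``binary=True`` the standard Shannon term for (1 - p) is
    added.
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        if binary:
            q = 1.0 - p
            h = h + np.where(q > 0, -q * np.log(np.where(q > 0, q, 1.0)), 0.0)
    return float(h) if h.ndim == 0 else h


def assign_genes_to_tads(tads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to the TAD containing its TSS (at most one).

    TADs must be non-overlapping per chromosome. Returns the annotation
    with a ``tad_id`` column; genes whose TSS falls outside every TAD get
    NaN and are tallied by the caller.
    """
    require_columns(tads, ["chrom", "start", "end", "tad_id"], "TAD table")
    require_columns(genes, ["gene_id", "chrom", "tss"], "annotation")
    _check_disjoint(tads, "TAD table")
    assigned = np.full(len(genes), None, dtype=object)
    for chrom, sub in tads.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        ids = sub["tad_id"].to_numpy()
        mask = (genes["chrom"] == chrom).to_numpy()
        tss = genes.loc[mask, "tss"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(starts, tss, side="right") - 1
        ok = (idx >= 0) & (tss < ends[np.clip(idx, 0, None)])
        out = np.full(len(tss), None, dtype=object)
        out[ok] = ids[idx[ok]]
        assigned[np.flatnonzero(mask)] = out
    result = genes.copy()
    result["tad_id"] = assigned
    return result


def tad_entropy(tads: pd.DataFrame,
                genes: pd.DataFrame,
                sexbiased: set[str] | list[str],
                binary: bool = False) -> pd.DataFrame:
    """Entropy of sex-biased gene content per TAD.

    Emits a record for every TAD (``n_genes``, ``n_sexbiased``, ``p``,
    ``entropy``) plus a ``has_sexbiased`` flag; the count of genes whose
    TSS lies outside every TAD is attached as ``DataFrame.attrs['n_unassigned']``.
    """
    sexbiased = set(sexbiased)
    assigned = assign_genes_to_tads(tads, genes)
    n_unassigned = int(assigned["tad_id"].isna().sum())
    inside = assigned.dropna(subset=["tad_id"])
    per_tad = inside.groupby("tad_id").agg(
        n_genes=("gene_id", "size"),
        n_sexbiased=("gene_id", lambda g: g.isin(sexbiased).sum()),
    )
    out = tads[["tad_id", "chrom", "start", "end"]].merge(
        per_tad, on="tad_id", how="left").fillna({"n_genes": 0, "n_sexbiased": 0})
    out["n_genes"] = out["n_genes"].astype(int)
    out["n_sexbiased"] = out["n_sexbiased"].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p"] = np.where(out["n_genes"] > 0,
                            out["n_sexbiased"] / out["n_genes"].replace(0, 1), 0.0)
    out["entropy"] = single_term_entropy(out["p"].to_numpy(), binary=binary)
    out["has_sexbiased"] = out["n_sexbiased"] > 0
    out.attrs["n_unassigned"] = n_unassigned
    return out


@dataclass
class TimingRegression:
    """OLS report for replication timing against sex bias."""

    mode: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int
    r_squared: float


def regress_timing_on_bias(rep_timing: pd.Series,
                           de_table: pd.DataFrame,
                           mode: str = "continuous") -> TimingRegression:
    """Regress per-gene replication timing on sex bias.

    ``mode='continuous'``: OLS of R on log2FC. ``mode='categorical'``: OLS
    of R on the bias label (female/male/unbiased) with unbiased as the
    reference level; the DE table must then carry a ``bias`` column.
    """
    frame = rep_timing.rename("rep_timing").rename_axis("gene_id").reset_index()
    merged = frame.merge(de_table, on="gene_id", how="inner").dropna(
        subset=["rep_timing"])
    if len(merged) < 3:
        raise ValueError("fewer than 3 genes with both replication timing and DE values")
    if mode == "continuous":
        require_columns(merged, ["log2fc"], "DE table")
        if np.ptp(merged["log2fc"].to_numpy()) == 0:
            raise ValueError("constant predictor: log2fc has no variation")
        fit = smf.ols("rep_timing ~ log2fc", data=merged).fit()
    elif mode == "categorical":
        require_columns(merged, ["bias"], "DE table")
        if merged["bias"].nunique() < 2:
            raise ValueError("constant predictor: bias has a single level")
        fit = smf.ols("rep_timing ~ C(bias, Treatment('unbiased'))", data=merged).fit()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TimingRegression(mode=mode, params=fit.params, bse=fit.bse,
                            pvalues=fit.pvalues, n=int(fit.nobs),
                            r_squared=float(fit.rsquared))


def interval_set_enrichment(gene_list: list[str],
                            reference_genes: list[str],
                            assigned: pd.DataFrame,
                            n_perm: int = 1000,
                            seed: int | None = None) -> pd.DataFrame:
    """Over-representation of a gene list within interval sets (e.g. TADs).

    ``assigned`` maps ``gene_id`` to an interval identifier column
    ``tad_id`` (from :func:`assign_genes_to_tads` or any band assignment).
    Reuses the gene-list permutation engine: per interval, observed member
    count vs. counts from uniformly redrawn same-size lists.
    """
    from .enrichment import permutation_test
    inside = assigned.dropna(subset=["tad_id"])
    fake = pd.DataFrame({
        "gene_id": inside["gene_id"],
        "tf_name": inside["tad_id"],
        "n_sites": 1,
    })
    result = permutation_test(gene_list, reference_genes, fake,
                              n_perm=n_perm, seed=seed, mode="genes")
    return result.rename(columns={"tf_name": "interval_id"})
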