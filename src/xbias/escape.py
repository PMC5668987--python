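"""Clonality-aware classification of X-inactivation escape.

Lymphoblastoid cell lines are often oligo- or monoclonal, so the same X is
inactive in most cells and silenced genes show allelic ratios skewed toward
1 by an individual-specific amount. The classifier absorbs that nuisance
with a per-individual null: for each sample, the mean ``mu`` and standard
deviation ``sigma`` of allelic ratios over a curated list of known silent
genes estimate where that sample's silenced genes sit. A gene whose
aggregated ratio falls significantly below Normal(mu, sigma) in an
individual is called escaping there; population-wide, a gene escaping in
more than ``cutoff`` (default 30%) of informative individuals is an escape
gene overall. The cutoff is calibrated by ROC against curated silent and
escape gene lists.

The per-individual test is one-sided (lower tail) by default: escape moves
ratios toward 0.5, strictly below the silent null on the [0.5, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import add_ratio_column
from .io import require_columns

DEFAULT_ALPHA = 0.05
DEFAULT_CUTOFF = 0.30
DEFAULT_MIN_INFORMATIVE = 5
DEFAULT_MIN_NULL_OBS = 10
DEFAULT_SIGMA_MIN = 0.01


@dataclass
class ClonalityNull:
    """Per-sample null for silenced-gene allelic ratios.

    ``mu``/``sigma`` summarize that sample's clonality; an unusable null
    (too few silent-gene observations) suppresses all calls for the sample.
    """

    sample_id: str
    mu: float
    sigma: float
    n_obs: int
    usable: bool


@dataclass
class CorrelationReport:
    """Pearson correlation between per-gene escape fraction and log2FC."""

    r: float
    p: float
    n: int


@dataclass
class RocCurve:
    """ROC of the population escape-fraction cutoff against curated lists.

    The positive class is *known silent*: sensitivity at cutoff ``c`` is the
    fraction of known silent genes correctly kept silent
    (``frac_escape <= c``); specificity is the fraction of known escape
    genes still called escape (``frac_escape > c``). ``chosen_cutoff``
    maximizes Youden's J (ties -> smallest cutoff).
    """

    table: pd.DataFrame  # columns cutoff, sensitivity, specificity
    auc: float
    chosen_cutoff: float


class InsufficientDataError(ValueError):
    pass


def fit_clonality_null(sites: pd.DataFrame,
                       silent_genes: list[str] | set[str],
                       sample_id: str,
                       min_null_obs: int = DEFAULT_MIN_NULL_OBS,
                       sigma_min: float = DEFAULT_SIGMA_MIN,
                       level: str = "site") -> ClonalityNull:
    """Estimate one sample's silent-gene ratio distribution.

    ``level='site'`` (default) pools per-site ratios across the sample's
    silent genes, maximizing the number of observations; ``level='gene'``
    uses per-gene coverage-weighted mean ratios instead. ``sigma`` is the
    sample standard deviation (ddof=1), floored at ``sigma_min`` so that
    monoclonal high-coverage samples cannot produce degenerate z-scores.
    """
    require_columns(sites, ["sample_id", "gene_id", "major_count", "total_count"],
                    "site table")
    silent = set(silent_genes)
    sub = sites[(sites["sample_id"] == sample_id)
                & sites["gene_id"].isin(silent)]
    sub = add_ratio_column(sub)
    if level == "gene":
        values = (sub.groupby("gene_id")
                  .apply(lambda g: np.average(g["ratio"], weights=g["total_count"]),
                         include_groups=False)
                  .to_numpy())
    elif level == "site":
        values = sub["ratio"].to_numpy()
    else:
        raise ValueError(f"unknown null estimation level {level!r}")
    n = len(values)
    if n < min_null_obs:
        return ClonalityNull(sample_id, float("nan"), float("nan"), n, False)
    mu = float(np.mean(values))
    sigma = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return ClonalityNull(sample_id, mu, max(sigma, sigma_min), n, True)


def test_gene(sample_id: str,
              gene_id: str,
              sites: pd.DataFrame,
              null: ClonalityNull,
              alpha: float = DEFAULT_ALPHA,
              weighted: bool = True,
              two_sided: bool = False) -> dict | None:
    """Test one gene in one sample against the clonality null.

    The gene-level ratio is the coverage-weighted mean of its site ratios
    (unweighted via ``weighted=False``). Returns a call record, or ``None``
    when the null is unusable or the gene has no sites in the sample
    (no-call, distinct from a silent call).
    """
    if not null.usable:
        return None
    sub = sites[(sites["sample_id"] == sample_id) & (sites["gene_id"] == gene_id)]
    if sub.empty:
        return None
    sub = add_ratio_column(sub)
    weights = sub["total_count"].to_numpy() if weighted else None
    ratio = float(np.average(sub["ratio"].to_numpy(), weights=weights))
    z = (ratio - null.mu) / null.sigma
    if two_sided:
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.cdf(z))
    return {
        "sample_id": sample_id, "gene_id": gene_id, "ratio": ratio,
        "z": z, "p": p, "escape_flag": bool(p < alpha), "n_sites": len(sub),
    }


def call_samples(sites: pd.DataFrame,
                 silent_genes: list[str] | set[str],
                 alpha: float = DEFAULT_ALPHA,
                 min_null_obs: int = DEFAULT_MIN_NULL_OBS,
                 sigma_min: float = DEFAULT_SIGMA_MIN,
                 null_level: str = "site",
                 weighted: bool = True,
                 two_sided: bool = False,
                 rescore_silent: bool = False,
                 ) -> tuple[pd.DataFrame, list[ClonalityNull]]:
    """Fit each sample's null and test every gene in every sample.

    Known silent genes define the null and are excluded from the output
    unless ``rescore_silent`` (diagnostic self-scoring). Returns the call
    table plus the fitted nulls.
    """
    silent = set(silent_genes)
    calls: list[dict] = []
    nulls: list[ClonalityNull] = []
    for sample_id, sample_sites in sites.groupby("sample_id", sort=True):
        null = fit_clonality_null(sample_sites, silent, sample_id,
                                  min_null_obs=min_null_obs,
                                  sigma_min=sigma_min, level=null_level)
        nulls.append(null)
        if not null.usable:
            continue
        genes = sorted(set(sample_sites["gene_id"]))
        for gene_id in genes:
            if gene_id in silent and not rescore_silent:
                continue
            call = test_gene(sample_id, gene_id, sample_sites, null,
                             alpha=alpha, weighted=weighted, two_sided=two_sided)
            if call is not None:
                calls.append(call)
    columns = ["sample_id", "gene_id", "ratio", "z", "p", "escape_flag", "n_sites"]
    return pd.DataFrame(calls, columns=columns), nulls


def aggregate_population(calls: pd.DataFrame,
                         cutoff: float = DEFAULT_CUTOFF,
                         min_informative: int = DEFAULT_MIN_INFORMATIVE,
                         annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summarize per-sample calls into population-level escape status.

    A gene is an escape gene when its escape fraction among informative
    samples is *strictly greater* than ``cutoff`` and it has at least
    ``min_informative`` informative samples; with fewer samples the status
    is ``insufficient_data`` (a value, not an error).
    """
    require_columns(calls, ["gene_id", "sample_id", "escape_flag"], "call table")
    grouped = calls.groupby("gene_id", sort=True)
    summary = pd.DataFrame({
        "n_informative": grouped["sample_id"].nunique(),
        "frac_escape": grouped["escape_flag"].mean(),
    }).reset_index()
    enough = summary["n_informative"] >= min_informative
    summary["population_call"] = np.where(
        ~enough, "insufficient_data",
        np.where(summary["frac_escape"] > cutoff, "escape", "silent"))
    if annotation is not None and "stratum" in annotation.columns:
        summary = summary.merge(annotation[["gene_id", "stratum"]],
                                on="gene_id", how="left")
    return summary


def roc_calibrate(frac_escape: pd.Series | pd.DataFrame,
                  known_escape: list[str],
                  known_silent: list[str],
                  grid: np.ndarray | None = None) -> RocCurve:
    """ROC over population-cutoff candidates against curated gene lists.

    ``frac_escape`` maps gene_id -> escape fraction (a Series, or a summary
    frame with ``gene_id``/``frac_escape`` columns). AUC is the trapezoidal
    area over (1 - specificity, sensitivity) anchored at (0, 0) and (1, 1).
    """
    if isinstance(frac_escape, pd.DataFrame):
        frac_escape = frac_escape.set_index("gene_id")["frac_escape"]
    esc = set(known_escape)
    sil = set(known_silent)
    if esc & sil:
        raise ValueError("known escape and silent lists overlap")
    esc_vals = frac_escape[frac_escape.index.isin(esc)].to_numpy(dtype=float)
    sil_vals = frac_escape[frac_escape.index.isin(sil)].to_numpy(dtype=float)
    if len(esc_vals) == 0 or len(sil_vals) == 0:
        raise InsufficientDataError(
            "both known lists must contain at least one gene with an escape fraction")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    # positive class = known silent: call silent when frac_escape <= c
    sens = np.array([(sil_vals <= c).mean() for c in grid])
    spec = np.array([(esc_vals > c).mean() for c in grid])
    fpr = 1.0 - spec
    # anchor endpoints then integrate along increasing false-positive rate
    pts = sorted(set(zip(fpr, sens)) | {(0.0, 0.0), (1.0, 1.0)})
    xs, ys = zip(*pts)
    auc = float(np.trapezoid(ys, xs))
    youden = sens + spec - 1.0
    chosen = float(grid[int(np.argmax(youden))])  # argmax takes first = smallest
    table = pd.DataFrame({"cutoff": grid, "sensitivity": sens, "specificity": spec})
    return RocCurve(table=table, auc=auc, chosen_cutoff=chosen)


def correlate_escape_with_bias(summaries: pd.DataFrame,
                               de_table: pd.DataFrame) -> CorrelationReport:
    """Pearson correlation between escape fraction and sex-bias log2FC."""
    require_columns(summaries, ["gene_id", "frac_escape"], "escape summary")
    require_columns(de_table, ["gene_id", "log2fc"], "DE table")
    merged = summaries.merge(de_table, on="gene_id", how="inner")
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} genes shared between escape summary and DE table")
    r, p = stats.pearsonr(merged["frac_escape"], merged["log2fc"])
    return CorrelationReport(r=float(r), p=float(p), n=len(merged))
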