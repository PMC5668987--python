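"""Permutation test for TF binding-site enrichment near a gene list.

Binding sites are split into proximal (overlapping the window within 2 kb
of a gene's TSS) and distal (everything else). For a query gene list (e.g.
female-biased sDEGs), each TF's observed proximal binding is compared with
a null built by redrawing same-sized gene lists uniformly without
replacement from a reference gene universe; the empirical p-value uses the
add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)``, which is
never zero.

"Binding" is counted per gene by default (number of listed genes with at
least one proximal site of the TF), which is robust to site clustering;
total-site counting is available via ``mode='sites'``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import require_columns

DEFAULT_WINDOW = 2000
DEFAULT_N_PERM = 1000


def assign_proximal(tfbs: pd.DataFrame,
                    genes: pd.DataFrame,
                    window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Count each TF's binding sites within ±``window`` bp of each TSS.

    A site is proximal to a gene iff its half-open interval overlaps the
    closed genomic span ``[TSS - window, TSS + window]`` (strand-agnostic).
    One site may be proximal to several genes. Returns rows
    ``(gene_id, tf_name, n_sites)`` with ``n_sites >= 1``.
    """
    require_columns(tfbs, ["chrom", "start", "end", "tf_name"], "TFBS table")
    require_columns(genes, ["gene_id", "chrom", "tss"], "annotation")
    if window <= 0:
        raise ValueError("window must be positive")
    trees: dict[str, IntervalTree] = {}
    skipped = 0
    for _, gene in genes.iterrows():
        if pd.isna(gene["tss"]):
            skipped += 1
            continue
        tss = int(gene["tss"])
        lo = max(0, tss - window)
        hi = tss + window + 1  # closed genomic span -> half-open
        trees.setdefault(gene["chrom"], IntervalTree()).addi(lo, hi, gene["gene_id"])
    if skipped:
        import warnings
        warnings.warn(f"{skipped} gene(s) without a TSS skipped", stacklevel=2)
    counts: dict[tuple[str, str], int] = {}
    for chrom, start, end, tf in zip(tfbs["chrom"], tfbs["start"],
                                     tfbs["end"], tfbs["tf_name"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(start), int(end)):
            key = (hit.data, tf)
            counts[key] = counts.get(key, 0) + 1
    rows = [(g, t, n) for (g, t), n in counts.items()]
    out = pd.DataFrame(rows, columns=["gene_id", "tf_name", "n_sites"])
    return out.sort_values(["gene_id", "tf_name"]).reset_index(drop=True)


def _count_matrix(assignments: pd.DataFrame,
                  genes: list[str]) -> tuple[np.ndarray, list[str]]:
    """Dense genes x TFs proximal-site count matrix over ``genes``."""
    tf_names = sorted(assignments["tf_name"].unique())
    gene_index = {g: i for i, g in enumerate(genes)}
    tf_index = {t: j for j, t in enumerate(tf_names)}
    mat = np.zeros((len(genes), len(tf_names)), dtype=np.int64)
    for g, t, n in zip(assignments["gene_id"], assignments["tf_name"],
                       assignments["n_sites"]):
        i = gene_index.get(g)
        if i is not None:
            mat[i, tf_index[t]] += int(n)
    return mat, tf_names


def observed_counts(gene_list: list[str],
                    assignments: pd.DataFrame,
                    mode: str = "genes") -> pd.Series:
    """Per-TF proximal binding over a gene list.

    ``mode='genes'``: number of listed genes with >= 1 proximal site of the
    TF. ``mode='sites'``: total proximal sites of the TF over the list.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    if mode not in ("genes", "sites"):
        raise ValueError(f"unknown count mode {mode!r}")
    mat, tf_names = _count_matrix(assignments, list(gene_list))
    counts = (mat > 0).sum(axis=0) if mode == "genes" else mat.sum(axis=0)
    return pd.Series(counts, index=tf_names, name="observed")


def permutation_test(gene_list: list[str],
                     reference_genes: list[str],
                     assignments: pd.DataFrame,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None,
                     mode: str = "genes") -> pd.DataFrame:
    """Gene-list permutation null for per-TF proximal binding.

    Each permutation draws ``len(gene_list)`` genes uniformly without
    replacement from ``reference_genes``. Returns one row per TF with the
    observed count, null mean/sd, fold change (observed / null mean;
    NaN-flagged when the null mean is zero), empirical ``p_perm``, and a
    Benjamini-Hochberg ``fdr`` column, sorted by ``p_perm``.
    """
    gene_list = list(gene_list)
    reference = list(dict.fromkeys(reference_genes))  # de-dup, keep order
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not gene_list:
        raise ValueError("gene list is empty")
    if len(gene_list) > len(reference):
        raise ValueError("gene list is larger than the reference universe")
    mat, tf_names = _count_matrix(assignments, reference)
    ref_index = {g: i for i, g in enumerate(reference)}
    missing = [g for g in gene_list if g not in ref_index]
    if missing:
        raise ValueError(f"gene list members missing from reference: {missing[:5]}")
    list_rows = np.array([ref_index[g] for g in gene_list])

    def count(rows: np.ndarray) -> np.ndarray:
        sub = mat[rows]
        return (sub > 0).sum(axis=0) if mode == "genes" else sub.sum(axis=0)

    observed = count(list_rows)
    rng = np.random.default_rng(seed)
    k = len(gene_list)
    null = np.empty((n_perm, len(tf_names)), dtype=np.int64)
    for b in range(n_perm):
        null[b] = count(rng.choice(len(reference), size=k, replace=False))
    n_ge = (null >= observed[None, :]).sum(axis=0)
    p_perm = (1.0 + n_ge) / (n_perm + 1.0)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(len(tf_names))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(null_mean > 0, observed / null_mean, np.nan)
    from statsmodels.stats.multitest import multipletests
    fdr = multipletests(p_perm, method="fdr_bh")[1]
    out = pd.DataFrame({
        "tf_name": tf_names,
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "fold_change": fold,
        "p_perm": p_perm,
        "fdr": fdr,
        "n_perm": n_perm,
    })
    return out.sort_values(["p_perm", "tf_name"]).reset_index(drop=True)


def select_sdeg_input(de_table: pd.DataFrame,
                      p_col: str = "p",
                      threshold: float = 0.05,
                      direction: str = "both") -> list[str]:
    """Gene list for enrichment: nominal ``p < threshold`` sDEGs.

    ``direction='female'`` keeps positive log2FC (female-biased),
    ``'male'`` negative, ``'both'`` their union. The inequality is strict.
    """
    require_columns(de_table, ["gene_id", "log2fc", p_col], "DE table")
    sig = de_table[de_table[p_col] < threshold]
    if direction == "female":
        sig = sig[sig["log2fc"] > 0]
    elif direction == "male":
        sig = sig[sig["log2fc"] < 0]
    elif direction != "both":
        raise ValueError(f"unknown direction {direction!r}")
    return sig["gene_id"].tolist()
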