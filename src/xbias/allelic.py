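"""Quality filtering and pileup of allelic observations at heterozygous sites.

The analysis-ready unit is the *allelic site*: for one sample at one
genotypically heterozygous exonic position, the read count of the major
(more-covered) allele and the total count. The allelic ratio
``major_count / total_count`` lies in [0.5, 1] by construction: near 1 under
monoallelic (silenced, clonal) expression, near 0.5 under biallelic
expression.

Quality filters follow the read-level criteria used for RNA-seq allelic
calls: edit distance to the reference NM <= 6, mapping quality MQ > 175
(an unconventional scale inherited from the upstream caller; the threshold
is a plain parameter here), site coverage >= 20, and exclusion of known
RNA-editing and non-uniquely-mappable regions.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import SchemaError, require_columns

DEFAULT_NM_MAX = 6
DEFAULT_MQ_MIN = 175
DEFAULT_MIN_COVERAGE = 20


def filter_reads(reads: pd.DataFrame,
                 nm_max: float = DEFAULT_NM_MAX,
                 mq_min: float = DEFAULT_MQ_MIN,
                 nm_col: str = "NM",
                 mq_col: str = "MQ") -> pd.DataFrame:
    """Keep observations with ``NM <= nm_max`` and ``MQ > mq_min``.

    Works on read-level tables (columns ``NM``/``MQ``) and, via the column
    arguments, on site-level tables carrying ``mean_NM``/``mean_MQ``.
    Row order is preserved; the operation is idempotent.
    """
    require_columns(reads, [nm_col, mq_col], "read table")
    mask = (reads[nm_col] <= nm_max) & (reads[mq_col] > mq_min)
    return reads.loc[mask].reset_index(drop=True)


def _annotation_trees(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    require_columns(annotation, ["gene_id", "chrom", "start", "end"], "annotation")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotation.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), g) for s, e, g in
            zip(sub["start"], sub["end"], sub["gene_id"]) if s < e)
    return trees


def pileup_sites(reads: pd.DataFrame,
                 het_sites: Iterable[tuple[str, str, int]],
                 annotation: pd.DataFrame,
                 strict: bool = False) -> pd.DataFrame:
    """Aggregate filtered reads into per-(sample, site) allele counts.

    ``het_sites`` is the set of genotypically heterozygous
    ``(sample_id, chrom, pos)`` triples; observations elsewhere are dropped.
    The major allele is the more-covered one; on an exact tie the
    lexicographically smaller base is labelled major (the ratio is 0.5
    either way). Sites inside overlapping genes are emitted once per gene
    with ``ambiguous=True`` (or dropped entirely when ``strict``).
    """
    require_columns(reads, ["sample_id", "chrom", "pos", "allele"], "read table")
    het = set(het_sites)
    trees = _annotation_trees(annotation)
    counts = (reads.groupby(["sample_id", "chrom", "pos", "allele"], sort=True)
              .size().reset_index(name="n"))
    rows = []
    n_ambiguous = 0
    for (sample, chrom, pos), group in counts.groupby(
            ["sample_id", "chrom", "pos"], sort=True):
        if (sample, chrom, pos) not in het:
            continue
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree[pos - 1])  # 1-based -> 0-based
        if not hits:
            continue
        total = int(group["n"].sum())
        best = group.sort_values(["n", "allele"], ascending=[False, True]).iloc[0]
        major = int(best["n"])
        if len(hits) > 1:
            n_ambiguous += 1
            if strict:
                continue
        for gene in hits:
            rows.append((sample, chrom, pos, gene, major, total,
                         True, len(hits) > 1))
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} heterozygous site(s) overlap more than one gene; "
            + ("dropped (strict mode)" if strict else "assigned to every overlapping gene"),
            stacklevel=2)
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "gene_id",
        "major_count", "total_count", "het_flag", "ambiguous"])


def _exclusion_trees(exclusion_beds: Sequence[pd.DataFrame]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for bed in exclusion_beds:
        require_columns(bed, ["chrom", "start", "end"], "exclusion BED")
        for chrom, sub in bed.groupby("chrom"):
            tree = trees.setdefault(chrom, IntervalTree())
            for s, e in zip(sub["start"], sub["end"]):
                if s < e:
                    tree.addi(int(s), int(e))
    return trees


def filter_sites(sites: pd.DataFrame,
                 exclusion_beds: Sequence[pd.DataFrame] = (),
                 min_cov: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Drop sites below ``min_cov`` total coverage or inside exclusion regions.

    Exclusion intervals are 0-based half-open; a site at 1-based position
    ``pos`` is excluded when ``pos - 1`` falls inside any interval.
    Idempotent and order-stable.
    """
    require_columns(sites, ["chrom", "pos", "total_count"], "site table")
    keep = sites["total_count"] >= min_cov
    if exclusion_beds:
        trees = _exclusion_trees(exclusion_beds)
        in_excl = np.fromiter(
            (bool(trees.get(c)) and bool(trees[c][p - 1])
             for c, p in zip(sites["chrom"], sites["pos"])),
            dtype=bool, count=len(sites))
        keep &= ~in_excl
    return sites.loc[keep].reset_index(drop=True)


def allelic_ratio(major_count, total_count):
    """Major-allele ratio ``major / total``, in [0.5, 1] by definition.

    Accepts scalars or array-likes. A zero total count is undefined.
    """
    major = np.asarray(major_count, dtype=float)
    total = np.asarray(total_count, dtype=float)
    if np.any(total <= 0):
        raise ValueError("allelic ratio undefined at zero total coverage")
    ratio = major / total
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def add_ratio_column(sites: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the site table with a ``ratio`` column appended."""
    require_columns(sites, ["major_count", "total_count"], "site table")
    out = sites.copy()
    out["ratio"] = allelic_ratio(out["major_count"].to_numpy(),
                                 out["total_count"].to_numpy())
    return out
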