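"""Synthetic cohorts, genome tracks, and gene-level covariate tables.

The generator emulates the statistical structure of the real study inputs
that the downstream stages assume, with known ground truth:

* allelic read counts at heterozygous exonic sites in a female LCL cohort,
  where each individual carries a clonality skew ``theta`` in [0.5, 1) that
  silenced genes follow and escape genes do not;
* a genome annotation with TFBS, replication-timing, and TAD tracks, where a
  designated subset of transcription factors binds preferentially within the
  proximal window of a target gene set;
* differential-expression and evolutionary covariate tables generated under
  stated linear models.

Randomness is driven by one seed per generator call; per-sample and
per-chromosome substreams are derived with :class:`numpy.random.SeedSequence`
spawn keys, so enlarging a cohort never reshuffles existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SpecError(ValueError):
    """A generator specification field is out of its valid range."""


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise SpecError(f"parameter {name!r} must be > 0, got {value!r}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: same (seed, key) -> same stream, always."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# specifications and truth


@dataclass
class CohortSpec:
    """Parameters of a synthetic allelic-expression cohort.

    ``clonality_alpha``/``clonality_beta`` shape the per-sample skew
    distribution ``theta = 0.5 + 0.5 * Beta(alpha, beta)`` on [0.5, 1).
    Silent genes follow ``theta``; escape genes follow
    ``escape_ratio_mean`` (near 0.5). Coverage per site is Poisson by
    default. ``sites_per_gene`` is the mean of a shifted Poisson
    (``1 + Poisson(mean - 1)``), so every gene keeps at least one site and
    a mean of exactly 1 yields exactly one site per gene.
    """

    n_samples: int = 50
    n_silent_genes: int = 100
    n_escape_genes: int = 20
    sites_per_gene: float = 3.0
    coverage_mean: float = 50.0
    clonality_alpha: float = 3.5
    clonality_beta: float = 1.5
    escape_ratio_mean: float = 0.5
    escape_penetrance: float = 1.0
    fail_fraction: float = 0.05
    coverage_model: str = "poisson"
    nbinom_dispersion: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SpecError(f"parameter 'n_samples' must be >= 1, got {self.n_samples}")
        for name in ("clonality_alpha", "clonality_beta", "coverage_mean",
                     "sites_per_gene", "nbinom_dispersion"):
            _check_positive(name, getattr(self, name))
        if not 0.5 <= self.escape_ratio_mean < 1.0:
            raise SpecError("parameter 'escape_ratio_mean' must lie in [0.5, 1)")
        if not 0.0 <= self.fail_fraction < 1.0:
            raise SpecError("parameter 'fail_fraction' must lie in [0, 1)")
        if not 0.0 <= self.escape_penetrance <= 1.0:
            raise SpecError("parameter 'escape_penetrance' must lie in [0, 1]")
        if self.coverage_model not in ("poisson", "nbinom"):
            raise SpecError("parameter 'coverage_model' must be 'poisson' or 'nbinom'")


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome with TFBS/replication/TAD tracks."""

    n_genes: int = 300
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 8_000_000})
    gene_length_mean: int = 20_000
    n_tfs: int = 20
    enriched_tf_ids: Sequence[str] = ()
    sites_per_tf: int = 400
    enrichment_hit_prob: float = 0.5
    proximal_window: int = 2000
    tad_size_mean: int = 800_000
    rep_segment_bp: int = 100_000
    rep_amplitude: float = 0.4
    n_exclusion_regions: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "gene_length_mean", "n_tfs", "sites_per_tf",
                     "proximal_window", "tad_size_mean", "rep_segment_bp"):
            _check_positive(name, getattr(self, name))
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise SpecError(f"chromosome {chrom!r} has non-positive length")
            if 2 * self.proximal_window >= length:
                raise SpecError(
                    f"proximal window {self.proximal_window} does not fit in {chrom!r}")


@dataclass
class TruthTable:
    """Ground truth behind one or more generator calls.

    Every simulated record traces to exactly one entry here: per-sample
    clonal skews, per-gene escape flags and sex-bias labels, per-TF
    enrichment flags, and the coefficient vectors behind covariate tables.
    """

    samples: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    tfs: pd.DataFrame | None = None
    coefficients: dict | None = None

    def merged(self, other: "TruthTable") -> "TruthTable":
        def pick(a, b):
            return b if b is not None else a
        genes = self.genes
        if genes is not None and other.genes is not None:
            genes = genes.merge(other.genes, on="gene_id", how="outer")
        else:
            genes = pick(self.genes, other.genes)
        return TruthTable(
            samples=pick(self.samples, other.samples),
            genes=genes,
            tfs=pick(self.tfs, other.tfs),
            coefficients=pick(self.coefficients, other.coefficients),
        )


# ---------------------------------------------------------------------------
# cohort simulation


def default_x_annotation(n_silent: int, n_escape: int,
                         gene_length: int = 20_000,
                         gap: int = 10_000) -> pd.DataFrame:
    """A minimal X-chromosome annotation with silent genes first."""
    n = n_silent + n_escape
    ids = [f"SIL{i + 1:04d}" for i in range(n_silent)]
    ids += [f"ESC{i + 1:04d}" for i in range(n_escape)]
    starts = np.arange(n, dtype=np.int64) * (gene_length + gap) + gap
    return pd.DataFrame({
        "gene_id": ids,
        "chrom": "chrX",
        "start": starts,
        "end": starts + gene_length,
        "tss": starts,
        "strand": "+",
        "stratum": "S5",
    })


def simulate_cohort(spec: CohortSpec,
                    annotation: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate per-site allelic counts for a female cohort.

    Returns an allelic site table (columns ``sample_id, chrom, pos, gene_id,
    major_count, total_count, mean_NM, mean_MQ``) and the :class:`TruthTable`
    with per-sample skews and per-gene escape flags.

    A fraction ``spec.fail_fraction`` of sites receives quality values
    (``mean_NM`` > 6 or ``mean_MQ`` <= 175) that the read-quality filter is
    expected to remove.
    """
    spec.validate()
    if annotation is None:
        annotation = default_x_annotation(spec.n_silent_genes, spec.n_escape_genes)
    n_genes = spec.n_silent_genes + spec.n_escape_genes
    if len(annotation) < n_genes:
        raise SpecError(
            f"annotation has {len(annotation)} genes; spec needs {n_genes}")
    genes = annotation.iloc[:n_genes].reset_index(drop=True)
    escape_flags = np.zeros(n_genes, dtype=bool)
    escape_flags[spec.n_silent_genes:] = True

    records = []
    thetas = np.empty(spec.n_samples)
    for s in range(spec.n_samples):
        rng = _rng(spec.seed, s)
        theta = 0.5 + 0.5 * rng.beta(spec.clonality_alpha, spec.clonality_beta)
        thetas[s] = theta
        sample_id = f"S{s + 1:04d}"
        n_sites = 1 + rng.poisson(spec.sites_per_gene - 1.0, size=n_genes)
        # per-gene escape penetrance: an escape gene may still be silenced
        # in a given individual
        escapes_here = escape_flags & (rng.random(n_genes) < spec.escape_penetrance)
        for g in range(n_genes):
            k = n_sites[g]
            if spec.coverage_model == "poisson":
                cov = rng.poisson(spec.coverage_mean, size=k)
            else:
                p = spec.nbinom_dispersion / (spec.nbinom_dispersion + spec.coverage_mean)
                cov = rng.negative_binomial(spec.nbinom_dispersion, p, size=k)
            cov = np.maximum(cov, 1)
            ratio = spec.escape_ratio_mean if escapes_here[g] else theta
            xa = rng.binomial(cov, ratio)
            major = np.maximum(xa, cov - xa)
            gene = genes.iloc[g]
            span = max(int(gene["end"]) - int(gene["start"]), k)
            offsets = np.sort(rng.choice(span, size=k, replace=False))
            failing = rng.random(k) < spec.fail_fraction
            nm = np.where(failing, 7 + rng.integers(0, 3, size=k),
                          rng.integers(0, 4, size=k))
            mq = np.where(failing, rng.uniform(50, 175, size=k),
                          rng.uniform(180, 254, size=k))
            for j in range(k):
                records.append((
                    sample_id, gene["chrom"], int(gene["start"]) + int(offsets[j]) + 1,
                    gene["gene_id"], int(major[j]), int(cov[j]),
                    float(nm[j]), round(float(mq[j]), 2),
                ))
    sites = pd.DataFrame(records, columns=[
        "sample_id", "chrom", "pos", "gene_id",
        "major_count", "total_count", "mean_NM", "mean_MQ"])
    truth = TruthTable(
        samples=pd.DataFrame({
            "sample_id": [f"S{s + 1:04d}" for s in range(spec.n_samples)],
            "theta": thetas}),
        genes=pd.DataFrame({
            "gene_id": genes["gene_id"].to_numpy(),
            "is_escape": escape_flags}),
    )
    return sites, truth


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(spec: GenomeSpec,
                    target_gene_set: Sequence[str] = (),
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               pd.DataFrame, TruthTable]:
    """Simulate annotation plus TFBS, replication-timing, and TAD tracks.

    Enriched TFs (``spec.enriched_tf_ids``) receive, on top of the uniform
    background shared by all TFs, one extra binding site in the proximal
    window of each target gene with probability ``enrichment_hit_prob``.
    Replication signal is piecewise-smooth per chromosome (sinusoid plus
    noise, clipped to [0, 1]); TADs tile each chromosome without overlap.

    Returns ``(annotation, tfbs, replication, tads, truth)``.
    """
    spec.validate()
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=np.int64)

    # --- genes: allocated to chromosomes proportionally to length
    alloc = np.maximum(1, np.round(spec.n_genes * lengths / lengths.sum()).astype(int))
    while alloc.sum() > spec.n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while alloc.sum() < spec.n_genes:
        alloc[int(np.argmax(lengths))] += 1
    gene_rows = []
    idx = 0
    for ci, chrom in enumerate(chroms):
        rng = _rng(spec.seed, 0, ci)
        n = int(alloc[ci])
        length = int(lengths[ci])
        glen = np.maximum(
            200, rng.poisson(spec.gene_length_mean, size=n)).astype(np.int64)
        starts = np.sort(rng.integers(0, np.maximum(1, length - glen.max()), size=n))
        for g in range(n):
            start = int(starts[g])
            end = min(start + int(glen[g]), length)
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            gene_rows.append((f"G{idx + 1:05d}", chrom, start, end, tss, strand, "NA"))
            idx += 1
    annotation = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "tss", "strand", "stratum"])

    targets = set(target_gene_set)
    unknown = targets - set(annotation["gene_id"])
    if unknown:
        raise SpecError(f"target genes not in simulated annotation: {sorted(unknown)[:5]}")

    # --- TFBS
    tf_names = [f"TF{i + 1:03d}" for i in range(spec.n_tfs)]
    enriched = set(spec.enriched_tf_ids)
    unknown_tf = enriched - set(tf_names)
    if unknown_tf:
        raise SpecError(f"enriched_tf_ids not among simulated TFs: {sorted(unknown_tf)}")
    probs = lengths / lengths.sum()
    target_rows = annotation[annotation["gene_id"].isin(targets)]
    tf_rows = []
    for ti, tf in enumerate(tf_names):
        rng = _rng(spec.seed, 1, ti)
        which = rng.choice(len(chroms), size=spec.sites_per_tf, p=probs)
        for ci in which:
            width = int(rng.integers(10, 30))
            start = int(rng.integers(0, lengths[ci] - width))
            tf_rows.append((chroms[ci], start, start + width, tf))
        if tf in enriched:
            for _, gene in target_rows.iterrows():
                if rng.random() < spec.enrichment_hit_prob:
                    width = int(rng.integers(10, 30))
                    low = max(0, int(gene["tss"]) - spec.proximal_window)
                    high = min(int(spec.chrom_lengths[gene["chrom"]]) - width,
                               int(gene["tss"]) + spec.proximal_window - width)
                    start = int(rng.integers(low, max(low + 1, high)))
                    tf_rows.append((gene["chrom"], start, start + width, tf))
    tfbs = pd.DataFrame(tf_rows, columns=["chrom", "start", "end", "tf_name"])

    # --- replication timing: piecewise segments with a smooth profile
    rep_rows = []
    for ci, chrom in enumerate(chroms):
        rng = _rng(spec.seed, 2, ci)
        length = int(lengths[ci])
        edges = np.arange(0, length, spec.rep_segment_bp, dtype=np.int64)
        edges = np.append(edges, length)
        phase = rng.uniform(0, 2 * np.pi)
        period = rng.uniform(8, 16)  # segments per full oscillation cycle
        for i in range(len(edges) - 1):
            value = (0.5 + spec.rep_amplitude * np.sin(2 * np.pi * i / period + phase)
                     + rng.normal(0, 0.02))
            rep_rows.append((chrom, int(edges[i]), int(edges[i + 1]),
                             float(np.clip(value, 0.0, 1.0))))
    replication = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "value"])

    # --- TADs: tile without overlap, last one truncated at the telomere
    tad_rows = []
    for ci, chrom in enumerate(chroms):
        rng = _rng(spec.seed, 3, ci)
        length = int(lengths[ci])
        pos = 0
        t = 0
        while pos < length:
            size = int(max(10_000, rng.normal(spec.tad_size_mean,
                                              0.2 * spec.tad_size_mean)))
            end = min(pos + size, length)
            tad_rows.append((chrom, pos, end, f"{chrom}_TAD{t + 1:03d}"))
            pos = end
            t += 1
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "tad_id"])

    truth = TruthTable(
        genes=pd.DataFrame({
            "gene_id": annotation["gene_id"].to_numpy(),
            "is_target": annotation["gene_id"].isin(targets).to_numpy()}),
        tfs=pd.DataFrame({"tf_name": tf_names,
                          "is_enriched": [t in enriched for t in tf_names]}),
    )
    return annotation, tfbs, replication, tads, truth


def simulate_exclusions(spec: GenomeSpec) -> pd.DataFrame:
    """Random short exclusion intervals (RNA-editing / low-mappability stand-ins)."""
    spec.validate()
    rows = []
    chroms = list(spec.chrom_lengths)
    for ci, chrom in enumerate(chroms):
        rng = _rng(spec.seed, 4, ci)
        for _ in range(spec.n_exclusion_regions):
            width = int(rng.integers(1, 200))
            start = int(rng.integers(0, spec.chrom_lengths[chrom] - width))
            rows.append((chrom, start, start + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# differential expression and covariate tables


DEFAULT_DE_PARAMS = {
    "effect_size": 1.0,     # |log2FC| mean for sex-biased genes
    "effect_sd": 0.3,
    "null_sd": 0.15,        # log2FC spread of unbiased genes
}


def simulate_de_table(gene_ids: Sequence[str],
                      n_female: int, n_male: int,
                      seed: int = 0,
                      effect_size: float = DEFAULT_DE_PARAMS["effect_size"],
                      effect_sd: float = DEFAULT_DE_PARAMS["effect_sd"],
                      null_sd: float = DEFAULT_DE_PARAMS["null_sd"],
                      frac_escape: Mapping[str, float] | None = None,
                      escape_slope: float = 0.0,
                      ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a female-vs-male differential-expression table.

    The first ``n_female`` genes get positive log2 fold changes, the next
    ``n_male`` negative ones; the rest are unbiased. If ``frac_escape`` and
    ``escape_slope`` are given, each gene's log2FC additionally receives
    ``escape_slope * frac_escape[gene]``, coupling sex bias to XCI escape.
    P values for biased genes are drawn small, for unbiased genes uniform;
    the FDR column is Benjamini-Hochberg.
    """
    gene_ids = list(gene_ids)
    if n_female + n_male > len(gene_ids):
        raise SpecError("n_female + n_male exceeds the number of genes")
    rng = _rng(seed, 5)
    n = len(gene_ids)
    bias = np.array(["unbiased"] * n, dtype=object)
    bias[:n_female] = "female"
    bias[n_female:n_female + n_male] = "male"
    log2fc = rng.normal(0.0, null_sd, size=n)
    log2fc[bias == "female"] = rng.normal(effect_size, effect_sd, size=n_female)
    log2fc[bias == "male"] = rng.normal(-effect_size, effect_sd, size=n_male)
    if frac_escape is not None:
        add = np.array([frac_escape.get(g, 0.0) for g in gene_ids])
        log2fc = log2fc + escape_slope * add
    p = rng.uniform(0, 1, size=n)
    biased = bias != "unbiased"
    p[biased] = 10.0 ** rng.uniform(-12, -3, size=int(biased.sum()))
    from statsmodels.stats.multitest import multipletests
    fdr = multipletests(p, method="fdr_bh")[1]
    de = pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "p": p, "fdr": fdr})
    truth = TruthTable(genes=pd.DataFrame({
        "gene_id": gene_ids, "bias": bias, "true_log2fc": log2fc}))
    return de, truth


#: default coefficient sets for the covariate generator; response-model
#: structure mirrors the association models the pipeline fits.
DEFAULT_DNDS_COEF = {
    "intercept": 0.28, "xcr": 0.0, "xy_pair": 0.0,
    "avg_expr": 0.0, "escape": 0.0, "disease": 0.0,
}
DEFAULT_BREADTH_COEF = {
    "intercept": 45.9, "female": -2.32, "male": -1.17,
    "dnds": -1.3, "avg_expr": 0.0,
}


def simulate_covariates(genes: pd.DataFrame,
                        dnds_coef: Mapping[str, float] | None = None,
                        breadth_coef: Mapping[str, float] | None = None,
                        noise_sd: float = 0.02,
                        breadth_noise_sd: float = 3.0,
                        integer_breadth: bool = False,
                        seed: int = 0) -> tuple[pd.DataFrame, TruthTable]:
    """Generate per-gene evolutionary covariates under stated linear models.

    ``genes`` needs ``gene_id`` and may carry ``is_escape`` and ``bias``
    truth columns (otherwise sampled). dN/dS follows the dnds coefficient
    model, breadth the breadth model; both with Gaussian noise. Breadth is
    clipped to the observable range [1, 56] (integer rounding optional).
    """
    if noise_sd < 0 or breadth_noise_sd < 0:
        raise SpecError("parameter 'noise_sd' must be >= 0")
    dnds_coef = dict(DEFAULT_DNDS_COEF, **(dnds_coef or {}))
    breadth_coef = dict(DEFAULT_BREADTH_COEF, **(breadth_coef or {}))
    rng = _rng(seed, 6)
    n = len(genes)
    gene_id = genes["gene_id"].to_numpy()
    escape = (genes["is_escape"].to_numpy().astype(bool)
              if "is_escape" in genes else rng.random(n) < 0.15)
    if "bias" in genes:
        bias = genes["bias"].to_numpy()
    else:
        bias = rng.choice(["female", "male", "unbiased"], size=n, p=[0.1, 0.1, 0.8])
    xy_pair = rng.random(n) < 0.1
    region = np.where(rng.random(n) < 0.5, "XCR", "XAR")
    disease = rng.random(n) < 0.2
    avg_expr = rng.gamma(2.0, 1.0, size=n)

    dnds = (dnds_coef["intercept"]
            + dnds_coef["xcr"] * (region == "XCR")
            + dnds_coef["xy_pair"] * xy_pair
            + dnds_coef["avg_expr"] * avg_expr
            + dnds_coef["escape"] * escape
            + dnds_coef["disease"] * disease
            + rng.normal(0, noise_sd, size=n))
    dnds = np.clip(dnds, 0.0, None)
    breadth = (breadth_coef["intercept"]
               + breadth_coef["female"] * (bias == "female")
               + breadth_coef["male"] * (bias == "male")
               + breadth_coef["dnds"] * dnds
               + breadth_coef["avg_expr"] * avg_expr
               + rng.normal(0, breadth_noise_sd, size=n))
    breadth = np.clip(breadth, 1.0, 56.0)
    if integer_breadth:
        breadth = np.round(breadth)
    records = pd.DataFrame({
        "gene_id": gene_id,
        "dnds": dnds,
        "xy_pair": xy_pair,
        "region": region,
        "avg_expr": avg_expr,
        "escape_status": np.where(escape, "escape", "non-escape"),
        "disease_flag": disease,
        "breadth": breadth,
        "bias": bias,
    })
    truth = TruthTable(coefficients={"dnds": dnds_coef, "breadth": breadth_coef})
    return records, truth


def ks_uniformity(pvalues: Sequence[float]) -> float:
    """KS-test p-value of the hypothesis that ``pvalues`` are U(0, 1)."""
    return float(stats.kstest(np.asarray(pvalues, dtype=float), "uniform").pvalue)
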