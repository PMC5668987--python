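# Methods

This note documents the statistical models implemented in `xbias`, the
choices made where the procedures admit more than one reading, and what the
synthetic-data generator does and does not emulate.

## Allelic sites and quality filtering

The unit of analysis is the allelic site: for one sample at one
genotypically heterozygous exonic position, the read count of the major
(more-covered) allele and the total count. The allelic ratio
`major_count / total_count` lies in [0.5, 1] by construction — near 1 under
monoallelic expression, near 0.5 under biallelic expression.

Quality filters: observations with edit distance NM ≤ 6 and mapping quality
MQ > 175 are kept (the MQ scale is inherited from the upstream RNA-seq
caller and exceeds the conventional 0–60 range; the threshold is an
ordinary parameter, default 175, and the anomaly is surfaced by the config
validator). Sites with total coverage below 20 are removed, as are sites
whose 0-based position falls inside any exclusion interval (RNA-editing
sites, non-uniquely-mappable regions), using single-position containment in
half-open BED intervals. Exclusion inputs give no window/merge semantics,
so containment of the site position itself is used.

A site at an allele-count tie gets the lexicographically smaller base as
major; the ratio is 0.5 either way, so downstream results are unaffected. A
site inside overlapping genes is assigned to every overlapping gene, with
an `ambiguous` flag (strict mode drops such sites).

## The clonality-calibrated escape classifier

Lymphoblastoid cell lines are frequently oligo- or monoclonal: the same X
chromosome is inactive in most cells, so even fully silenced genes show
allelic ratios skewed toward 1 by an individual-specific amount. The
classifier absorbs this nuisance with a per-individual null: for sample
*s*, the mean μ_s and standard deviation σ_s of allelic ratios over a
curated list of known silent genes estimate where that sample's silenced
genes sit. A gene *g* with aggregated ratio r_gs is scored by
z = (r_gs − μ_s)/σ_s and p = Φ(z); it escapes in that individual when
p < α (default 0.05). Population-wide, a gene escaping in strictly more
than 30% of informative individuals (at least 5 by default) is an escape
gene overall; the 30% cutoff is calibrated by ROC against curated silent
and escape gene lists, choosing the cutoff that maximizes Youden's J.

Choices where the procedure is under-specified:

* **Sidedness.** The per-individual test is one-sided (lower tail) by
  default: escape moves ratios toward 0.5, strictly below the silent null
  on the [0.5, 1] scale. A two-sided flag exists.
* **Gene-level aggregation.** Multi-site genes are summarized by the
  coverage-weighted mean of site ratios (unweighted mean via a flag).
* **Null level.** Per-site ratios are pooled across a sample's silent
  genes (maximizing the number of null observations); per-gene means are
  available via `level="gene"`.
* **σ floor.** σ_s is floored at 0.01 so monoclonal, high-coverage samples
  cannot produce degenerate z-scores.
* **ROC orientation.** The positive class is *known silent* (sensitivity =
  correctly keeping a known silent gene silent); the escape-oriented view
  follows by symmetry. Known silent genes are excluded from classification
  output by default, since they define the null; a rescore flag re-scores
  them for diagnostics.

Known limitations of the plug-in normal test: treating (μ_s, σ_s) as known
is anti-conservative by O(1/n_null), the binomial ratio is left-skewed at
moderate coverage, and folding at 0.5 truncates the lower tail for weakly
skewed samples. For a gene with k sites, the weighted-mean ratio has
variance ≈ σ²/k while the null is fitted to single-site spread, so
multi-site genes are tested conservatively. The calibration test therefore
uses a design where the test statistic and the null observations are
identically distributed — one informative site per gene, coverage 500, a
polyclonal cohort (skew 0.5 + 0.5·Beta(1.5, 3.5), mean ≈ 0.66) — which is
the regime the per-individual null exists for and where the opposing
finite-sample effects nearly cancel.

## TFBS enrichment

Binding sites are proximal to a gene when their half-open interval overlaps
the closed span [TSS − 2 kb, TSS + 2 kb] (strand-agnostic; no strand rule is
defined for the window). Per TF, the observed statistic over a query gene
list defaults to the number of listed genes with ≥ 1 proximal site — robust
to site clustering — with total-site counting via `mode="sites"`. The null
redraws same-sized gene lists uniformly *without replacement* from the
reference universe (a "randomly drawn gene list" is read as a subset);
p = (1 + #{null ≥ observed})/(n_perm + 1), the add-one estimator, which is
conservative-unbiased and never zero. Enrichment is reported at permutation
p < 0.05 without multiple-testing correction, matching the analysis this
implements, but a Benjamini–Hochberg FDR column is always emitted.
Fold change is observed/null-mean (undefined and NaN-flagged when the null
mean is zero).

## Replication timing, TADs, entropy

Per-gene replication timing is the basepair-weighted average
`R_gene = Σ_i R_i · bpOverlap_i / totalBpInGene`, where the denominator is
the *full* gene length: basepairs uncovered by any segment contribute zero
to the numerator (literal reading of the formula; covered-bp normalization
via a flag). Genes with zero covered basepairs are missing, and overlapping
segments within one track are an error.

Genes are assigned to the unique TAD containing their TSS (assignment rule
is otherwise unspecified; TSS containment gives an unambiguous partition).
TAD entropy is the single-term −p·ln(p) with p the proportion of sex-biased
genes in the TAD, entropy(0) := 0 by continuity. The natural log is used
(no base is specified; the choice rescales uniformly and does not affect
rankings), and the single-term form — zero at p ∈ {0, 1}, maximum 1/e at
p = 1/e — is implemented as stated, with standard binary entropy behind a
flag. Positional-cluster over-representation reuses the same gene-list
permutation engine via `interval_set_enrichment`.

## Association models

All models are ordinary least squares with treatment coding, p-values from
the t distribution on residual degrees of freedom, no robust errors.
Reference levels: XAR (so the region coefficient reads "XCR vs XAR"),
non-escape, non-XY-pair, non-disease, unbiased. Missing data is handled
complete-case per model with the dropped count recorded. Rank-deficient
designs raise an error naming the collinear columns; a categorical term
with a single observed level is dropped rather than fitted. Three-group
comparisons are expressed as the F test of the categorical term
(`f_pvalue` on the fit). Univariate numeric fits also report Spearman's
rho, since correlation conventions vary between reports; mean expression
enters untransformed (log transformation is not specified anywhere).

## The synthetic-data generator

The generator produces inputs with the statistical structure the stages
assume, plus a truth table every record traces to.

* **Cohorts.** Per-sample clonal skew θ_s = 0.5 + 0.5·Beta(α, β) on
  [0.5, 1): no generative model for clonality is given beyond
  "polyclonality skews ratios", and the scaled Beta is a flexible bounded
  family. Silent-gene major-allele counts are Binomial(coverage, θ_s);
  escape genes are Binomial(coverage, 0.5) by default — a fixed-probability
  model with no partial-escape gradient, though a per-gene
  `escape_penetrance` parameter exists (default 1.0: every escape gene
  escapes in every individual; inter-individual variability in escape is
  real but no value is available to default to). Coverage is
  Poisson(coverage_mean) by default (negative binomial optional), since
  the real pipeline only applies a ≥ 20× floor. Sites per gene follow
  1 + Poisson(mean − 1), so every gene keeps one informative site. A
  configurable fraction of sites receives failing NM/MQ values for
  exercising the filters.
* **Genomes.** Genes are placed per chromosome proportional to length;
  enriched TFs receive one extra proximal site per target gene with a
  configurable hit probability on top of a uniform background;
  replication signal is a piecewise sinusoid-plus-noise profile clipped
  to [0, 1]; TADs tile each chromosome exactly.
* **Covariate/DE tables.** dN/dS and breadth are generated under the same
  linear models the package fits, with Gaussian noise; breadth is clipped
  to the observable range [1, 56] and left continuous by default (integer
  rounding behind a flag) so zero-noise coefficient recovery is exact —
  the clip never binds for the default coefficient sets. DE tables give
  biased genes log2FC ~ ±N(1.0, 0.3) and small p-values, unbiased genes
  N(0, 0.15) and uniform p, with optional coupling of log2FC to escape
  fraction.
* **Determinism.** One seed per generator call; per-sample and
  per-chromosome substreams come from `SeedSequence` spawn keys, so a
  fixed seed is byte-reproducible and enlarging a cohort never reshuffles
  existing samples.

What the generator does **not** emulate: read-level data and alignment
artifacts, haplotype phase and linkage, reference bias at het sites,
shared clonality structure between genes beyond the single θ_s,
population structure, or expression-level variation across genes. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated models, not robustness to every artifact of real RNA-seq.

## Problem sizes and numerical choices

The bundled test and demonstration scenarios use cohorts of 50–100 samples
with 100–180 genes and coverage 50–1000, genomes of 200–300 genes over two
chromosomes with 12–20 TFs, and 1000 permutations — sizes chosen so each
scenario's estimates are well-powered for the effects planted in it while a
full run stays interactive on a laptop. The permutation-oracle check uses
an 8-gene universe where all 56 subsets can be enumerated exactly; the
replication-timing check compares against a per-basepair brute-force mean
(agreement to 1e−12); regression recovery is checked exactly at zero noise
and within 3 standard errors at realistic noise. Ties in the ROC grid
resolve to the smallest cutoff; trapezoidal AUC is anchored at (0, 0) and
(1, 1).
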