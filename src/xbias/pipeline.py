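"""End-to-end orchestration: simulate -> filter -> escape -> enrich -> features -> regress.

A run is driven by a :class:`RunConfig` (loadable from YAML). One seed fans
out into per-stage substreams, so the whole run is reproducible and each
stage is independently reproducible. All outputs are header-rowed TSVs plus
a JSON manifest recording the package version, parameters, seed, and sha256
checksums of every input and output; nothing time-dependent is written, so
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import allelic, enrichment, escape, features, models, synthetic
from .io import (read_bed, read_gene_list, read_table, sha256_of, write_bed,
                 write_gene_list, write_table)

log = logging.getLogger("xbias")

STAGES = ["simulate", "filter", "escape", "enrich", "features", "regress"]

DEFAULT_PARAMS = {
    "alpha": 0.05,
    "cutoff": 0.30,
    "min_informative": 5,
    "min_null_obs": 10,
    "sigma_min": 0.01,
    "min_cov": 20,
    "nm_max": 6,
    "mq_min": 175,
    "window": 2000,
    "n_perm": 1000,
    "direction": "female",
    "known_silent_fraction": 0.6,
    "known_escape_fraction": 0.5,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "xbias_run"
    seed: int = 7
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    genome: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def param(self, name: str):
        return self.params.get(name, DEFAULT_PARAMS[name])


def validate_config(config: RunConfig) -> list[dict]:
    """Schema and range checks; returns a report, never raises."""
    report: list[dict] = []

    def entry(level: str, message: str) -> None:
        report.append({"level": level, "message": message})

    for stage in config.stages:
        if stage not in STAGES:
            entry("error", f"unknown stage {stage!r}")
    alpha = config.param("alpha")
    if not 0 < alpha < 1:
        entry("error", f"alpha must lie in (0, 1), got {alpha}")
    cutoff = config.param("cutoff")
    if not 0 <= cutoff <= 1:
        entry("error", f"cutoff must lie in [0, 1], got {cutoff}")
    else:
        entry("info", f"population escape cutoff = {cutoff}")
    if config.param("n_perm") < 1:
        entry("error", "n_perm must be >= 1")
    if config.param("min_cov") < 1:
        entry("error", "min_cov must be >= 1")
    mq_min = config.param("mq_min")
    if mq_min > 60:
        entry("info",
              f"mq_min = {mq_min} exceeds conventional mapping-quality ranges; "
              "this matches the upstream caller's printed scale")
    if "simulate" not in config.stages:
        needed = {"filter": ["sites"], "escape": ["silent_genes"],
                  "enrich": ["tfbs", "annotation", "de_table"],
                  "features": ["annotation", "replication", "tads", "de_table"],
                  "regress": ["covariates"]}
        for stage, keys in needed.items():
            if stage not in config.stages:
                continue
            for key in keys:
                path = config.inputs.get(key)
                if path is None:
                    entry("error", f"stage {stage!r} needs input {key!r}")
                elif not Path(path).exists():
                    entry("error", f"input file for {key!r} not found: {path}")
    if not any(e["level"] == "error" for e in report):
        entry("info", "configuration is valid")
    return report


class StageDependencyError(RuntimeError):
    pass


def _simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate every synthetic input and return their paths."""
    seed = config.seed
    indir = outdir / "inputs"
    cohort_spec = synthetic.CohortSpec(seed=seed, **config.cohort)
    sites, cohort_truth = synthetic.simulate_cohort(cohort_spec)
    x_annotation = synthetic.default_x_annotation(
        cohort_spec.n_silent_genes, cohort_spec.n_escape_genes)

    genome_kwargs = dict(config.genome)
    genome_kwargs.setdefault("n_tfs", 12)
    genome_kwargs.setdefault("n_genes", 200)
    genome_spec = synthetic.GenomeSpec(seed=seed + 1, **genome_kwargs)
    # targets for planted TF enrichment: the genes that will be female-biased
    n_female = max(10, genome_spec.n_genes // 10)
    n_male = max(10, genome_spec.n_genes // 12)
    if not genome_spec.enriched_tf_ids:
        genome_spec.enriched_tf_ids = ["TF001", "TF002"]
    pre_ids = [f"G{i + 1:05d}" for i in range(n_female)]
    annotation, tfbs, replication, tads, genome_truth = synthetic.simulate_genome(
        genome_spec, target_gene_set=pre_ids)
    de, de_truth = synthetic.simulate_de_table(
        annotation["gene_id"], n_female, n_male, seed=seed + 2)

    genes_for_cov = de_truth.genes.copy()
    covariates, cov_truth = synthetic.simulate_covariates(
        genes_for_cov, seed=seed + 3)

    silent_ids = cohort_truth.genes.loc[~cohort_truth.genes["is_escape"], "gene_id"]
    escape_ids = cohort_truth.genes.loc[cohort_truth.genes["is_escape"], "gene_id"]
    n_known_silent = max(1, int(len(silent_ids) * config.param("known_silent_fraction")))
    n_known_escape = max(1, int(len(escape_ids) * config.param("known_escape_fraction")))
    known_silent = silent_ids.iloc[:n_known_silent].tolist()
    known_escape = escape_ids.iloc[:n_known_escape].tolist()

    paths = {
        "sites": indir / "allelic_sites.tsv",
        "x_annotation": indir / "x_annotation.tsv",
        "annotation": indir / "annotation.tsv",
        "silent_genes": indir / "known_silent.txt",
        "escape_genes": indir / "known_escape.txt",
        "tfbs": indir / "tfbs.bed",
        "replication": indir / "replication.bed",
        "tads": indir / "tads.bed",
        "de_table": indir / "de_table.tsv",
        "covariates": indir / "covariates.tsv",
        "truth_samples": indir / "truth_samples.tsv",
        "truth_genes": indir / "truth_genes.tsv",
    }
    write_table(sites, paths["sites"])
    write_table(x_annotation, paths["x_annotation"])
    write_table(annotation, paths["annotation"])
    write_gene_list(known_silent, paths["silent_genes"])
    write_gene_list(known_escape, paths["escape_genes"])
    write_bed(tfbs, paths["tfbs"], extra_columns=["tf_name"])
    write_bed(replication, paths["replication"], extra_columns=["value"])
    write_bed(tads, paths["tads"], extra_columns=["tad_id"])
    write_table(de, paths["de_table"])
    write_table(covariates, paths["covariates"])
    write_table(cohort_truth.samples, paths["truth_samples"])
    write_table(cohort_truth.genes, paths["truth_genes"])
    return {key: str(path) for key, path in paths.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_config(config)
    errors = [e for e in report if e["level"] == "error"]
    if errors:
        raise StageDependencyError("; ".join(e["message"] for e in errors))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": {key: config.param(key) for key in DEFAULT_PARAMS},
        "stages": {},
    }
    inputs = dict(config.inputs)
    ordered = [s for s in STAGES if s in config.stages]
    try:
        for stage in ordered:
            log.info("stage %s", stage)
            outputs = _run_stage(stage, config, inputs, outdir)
            manifest["stages"][stage] = {
                "status": "ok",
                "outputs": {k: {"path": v, "sha256": sha256_of(v)}
                            for k, v in outputs.items()},
            }
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _run_stage(stage: str, config: RunConfig, inputs: dict, outdir: Path) -> dict:
    if stage == "simulate":
        produced = _simulate_stage(config, outdir)
        inputs.update(produced)
        return produced

    if stage == "filter":
        if "sites" not in inputs:
            raise StageDependencyError("filter stage needs a sites table")
        sites = read_table(inputs["sites"])
        nm_col = "mean_NM" if "mean_NM" in sites.columns else "NM"
        mq_col = "mean_MQ" if "mean_MQ" in sites.columns else "MQ"
        kept = allelic.filter_reads(sites, nm_max=config.param("nm_max"),
                                    mq_min=config.param("mq_min"),
                                    nm_col=nm_col, mq_col=mq_col)
        beds = [read_bed(p) for p in inputs.get("exclusions", [])]
        kept = allelic.filter_sites(kept, exclusion_beds=beds,
                                    min_cov=config.param("min_cov"))
        path = outdir / "filtered_sites.tsv"
        write_table(kept, path)
        inputs["filtered_sites"] = str(path)
        return {"filtered_sites": str(path)}

    if stage == "escape":
        if "filtered_sites" not in inputs:
            raise StageDependencyError("escape stage needs filtered sites (run filter)")
        sites = read_table(inputs["filtered_sites"])
        silent = read_gene_list(inputs["silent_genes"])
        calls, _ = escape.call_samples(
            sites, silent, alpha=config.param("alpha"),
            min_null_obs=config.param("min_null_obs"),
            sigma_min=config.param("sigma_min"))
        summary = escape.aggregate_population(
            calls, cutoff=config.param("cutoff"),
            min_informative=config.param("min_informative"))
        outputs = {}
        calls_path = outdir / "escape_calls.tsv"
        summary_path = outdir / "escape_summary.tsv"
        write_table(calls, calls_path)
        write_table(summary, summary_path)
        outputs["calls"] = str(calls_path)
        outputs["summary"] = str(summary_path)
        inputs["escape_summary"] = str(summary_path)
        if inputs.get("escape_genes"):
            known_escape = read_gene_list(inputs["escape_genes"])
            rescored, _ = escape.call_samples(
                sites, silent, alpha=config.param("alpha"),
                min_null_obs=config.param("min_null_obs"),
                sigma_min=config.param("sigma_min"), rescore_silent=True)
            full = escape.aggregate_population(
                rescored, cutoff=config.param("cutoff"),
                min_informative=config.param("min_informative"))
            roc = escape.roc_calibrate(full, known_escape, silent)
            roc_path = outdir / "roc.tsv"
            roc_table = roc.table.copy()
            roc_table["auc"] = roc.auc
            roc_table["chosen_cutoff"] = roc.chosen_cutoff
            write_table(roc_table, roc_path)
            outputs["roc"] = str(roc_path)
        return outputs

    if stage == "enrich":
        de = read_table(inputs["de_table"])
        annotation = read_table(inputs["annotation"])
        tfbs = read_bed(inputs["tfbs"], extra_names=["tf_name"])
        gene_list = enrichment.select_sdeg_input(
            de, direction=config.param("direction"))
        assignments = enrichment.assign_proximal(
            tfbs, annotation, window=config.param("window"))
        result = enrichment.permutation_test(
            gene_list, annotation["gene_id"].tolist(), assignments,
            n_perm=config.param("n_perm"), seed=config.seed + 10)
        path = outdir / "tf_enrichment.tsv"
        write_table(result, path)
        return {"enrichment": str(path)}

    if stage == "features":
        annotation = read_table(inputs["annotation"])
        replication = read_bed(inputs["replication"], extra_names=["value"])
        replication["value"] = replication["value"].astype(float)
        tads = read_bed(inputs["tads"], extra_names=["tad_id"])
        de = read_table(inputs["de_table"])
        timing = features.replication_timing_per_gene(annotation, replication)
        timing_path = outdir / "rep_timing.tsv"
        write_table(timing.rename_axis("gene_id").reset_index(), timing_path)
        sexbiased = set(enrichment.select_sdeg_input(de, direction="both"))
        tad_table = features.tad_entropy(tads, annotation, sexbiased)
        tad_path = outdir / "tad_entropy.tsv"
        write_table(tad_table, tad_path)
        reg = features.regress_timing_on_bias(timing, de, mode="continuous")
        reg_path = outdir / "timing_regression.tsv"
        write_table(pd.DataFrame({
            "term": reg.params.index, "beta": reg.params.to_numpy(),
            "se": reg.bse.to_numpy(), "p": reg.pvalues.to_numpy()}), reg_path)
        return {"rep_timing": str(timing_path), "tad_entropy": str(tad_path),
                "timing_regression": str(reg_path)}

    if stage == "regress":
        records = read_table(inputs["covariates"])
        outputs = {}
        for name, fit in (
                ("dnds_model", models.fit_dnds_model(records)),
                ("breadth_model", models.fit_breadth_model(records)),
                ("univariate_breadth_dnds",
                 models.fit_univariate(records, "dnds", "breadth"))):
            path = outdir / f"{name}.tsv"
            write_table(fit.to_frame(), path)
            outputs[name] = str(path)
        return outputs

    raise ValueError(f"unknown stage {stage!r}")


def demo(outdir: str | Path, seed: int = 7,
         cohort: dict | None = None, genome: dict | None = None) -> dict:
    """One-command synthetic demonstration run of every stage."""
    config = RunConfig(outdir=str(outdir), seed=seed,
                       cohort=cohort or {}, genome=genome or {})
    return run_pipeline(config)
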