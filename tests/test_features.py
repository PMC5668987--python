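import math

import numpy as np
import pandas as pd
import pytest

from xbias import features


def make_genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "tss"])


def make_track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def brute_force_timing(gene_start, gene_end, segments, normalize_covered=False):
    """Per-basepair oracle: walk every base of the gene."""
    total = 0.0
    covered = 0
    for bp in range(gene_start, gene_end):
        for _, seg in segments.iterrows():
            if seg["start"] <= bp < seg["end"]:
                total += seg["value"]
                covered += 1
                break
    if covered == 0:
        return float("nan")  # no overlap -> missing, matching the contract
    denom = covered if normalize_covered else (gene_end - gene_start)
    return total / denom


class TestReplicationTiming:
    def test_printed_arithmetic(self):
        genes = make_genes([("G", "chr1", 0, 1000, 0)])
        track = make_track([("chr1", 0, 400, 0.2), ("chr1", 400, 1000, 0.8)])
        out = features.replication_timing_per_gene(genes, track)
        assert out["G"] == pytest.approx((0.2 * 400 + 0.8 * 600) / 1000)
        assert out["G"] == pytest.approx(0.56)

    def test_gene_inside_one_segment(self):
        genes = make_genes([("G", "chr1", 5000, 6000, 5000)])
        track = make_track([("chr1", 0, 100_000, 0.37)])
        out = features.replication_timing_per_gene(genes, track)
        assert out["G"] == pytest.approx(0.37)

    def test_uncovered_bases_count_in_denominator(self):
        genes = make_genes([("G", "chr1", 0, 1000, 0)])
        track = make_track([("chr1", 0, 500, 1.0)])
        literal = features.replication_timing_per_gene(genes, track)
        assert literal["G"] == pytest.approx(0.5)
        covered = features.replication_timing_per_gene(genes, track,
                                                       normalize_covered=True)
        assert covered["G"] == pytest.approx(1.0)

    def test_fully_uncovered_gene_missing(self):
        genes = make_genes([("G", "chr1", 0, 1000, 0), ("H", "chr9", 0, 10, 0)])
        track = make_track([("chr1", 5000, 6000, 0.4)])
        out = features.replication_timing_per_gene(genes, track)
        assert out.isna().all()

    def test_overlapping_segments_rejected(self):
        genes = make_genes([("G", "chr1", 0, 1000, 0)])
        track = make_track([("chr1", 0, 500, 0.1), ("chr1", 400, 900, 0.2)])
        with pytest.raises(features.TrackError, match="overlap"):
            features.replication_timing_per_gene(genes, track)

    def test_invariant_to_segment_splitting(self):
        genes = make_genes([("G", "chr1", 100, 900, 100)])
        track = make_track([("chr1", 0, 600, 0.3), ("chr1", 600, 1000, 0.7)])
        split = make_track([("chr1", 0, 200, 0.3), ("chr1", 200, 600, 0.3),
                            ("chr1", 600, 800, 0.7), ("chr1", 800, 1000, 0.7)])
        a = features.replication_timing_per_gene(genes, track)
        b = features.replication_timing_per_gene(genes, split)
        assert a["G"] == pytest.approx(b["G"], abs=1e-15)

    def test_matches_per_basepair_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            edges = np.sort(rng.choice(np.arange(1, 2000), size=6, replace=False))
            segs = []
            pos = 0
            for e in edges:
                if rng.random() < 0.7:  # leave some gaps uncovered
                    segs.append(("chr1", pos, int(e), float(rng.uniform(0, 1))))
                pos = int(e)
            track = make_track(segs)
            start = int(rng.integers(0, 1500))
            end = start + int(rng.integers(50, 400))
            genes = make_genes([("G", "chr1", start, end, start)])
            got = features.replication_timing_per_gene(genes, track)["G"]
            want = brute_force_timing(start, end, track)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestEntropy:
    def test_closed_forms(self):
        assert features.single_term_entropy(1.0) == 0.0
        assert features.single_term_entropy(0.0) == 0.0
        assert features.single_term_entropy(0.5) == pytest.approx(0.5 * math.log(2))
        assert features.single_term_entropy(1 / math.e) == pytest.approx(1 / math.e)

    def test_maximum_at_one_over_e(self):
        grid = np.linspace(1e-6, 1, 10_000)
        values = features.single_term_entropy(grid)
        assert values.max() <= 1 / math.e + 1e-9
        assert grid[np.argmax(values)] == pytest.approx(1 / math.e, abs=1e-3)

    def test_nonnegative_and_zero_at_endpoints_only(self):
        grid = np.linspace(0, 1, 1001)
        values = features.single_term_entropy(grid)
        assert (values >= 0).all()
        interior = values[1:-1]
        assert (interior > 0).all()

    def test_binary_mode(self):
        assert features.single_term_entropy(0.5, binary=True) == pytest.approx(
            math.log(2))


class TestTads:
    def make_tads(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [0, 1000, 0],
            "end": [1000, 3000, 5000],
            "tad_id": ["T1", "T2", "T3"]})

    def make_genes(self):
        return pd.DataFrame({
            "gene_id": ["A", "B", "C", "D", "E"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr1"],
            "tss": [10, 999, 1500, 100, 5000]})  # E outside every TAD

    def test_assignment_partitions_genes(self):
        assigned = features.assign_genes_to_tads(self.make_tads(), self.make_genes())
        by_gene = assigned.set_index("gene_id")["tad_id"]
        assert by_gene["A"] == "T1" and by_gene["B"] == "T1"
        assert by_gene["C"] == "T2" and by_gene["D"] == "T3"
        assert pd.isna(by_gene["E"])

    def test_entropy_table(self):
        out = features.tad_entropy(self.make_tads(), self.make_genes(), {"A"})
        row = out.set_index("tad_id").loc["T1"]
        assert row["n_genes"] == 2 and row["n_sexbiased"] == 1
        assert row["p"] == pytest.approx(0.5)
        assert row["entropy"] == pytest.approx(0.5 * math.log(2))
        assert out.attrs["n_unassigned"] == 1
        t2 = out.set_index("tad_id").loc["T2"]
        assert t2["entropy"] == 0.0  # p = 1 -> -1 * ln(1) = 0

    def test_overlapping_tads_rejected(self):
        tads = self.make_tads()
        tads.loc[1, "start"] = 500
        with pytest.raises(features.TrackError, match="overlap"):
            features.tad_entropy(tads, self.make_genes(), set())


class TestTimingRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        log2fc = rng.normal(0, 1, 50)
        timing = pd.Series(2.0 * log2fc + 0.5,
                           index=[f"G{i}" for i in range(50)])
        de = pd.DataFrame({"gene_id": timing.index, "log2fc": log2fc})
        fit = features.regress_timing_on_bias(timing, de)
        assert fit.params["log2fc"] == pytest.approx(2.0)
        assert fit.params["Intercept"] == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_equal_group_means_give_zero_coefficients(self):
        genes = [f"G{i}" for i in range(27)]
        # each bias group sees the same {0.2, 0.5, 0.8} pattern -> equal means
        timing = pd.Series(np.tile([0.2, 0.5, 0.8], 9), index=genes)
        de = pd.DataFrame({"gene_id": genes,
                           "bias": np.repeat(["female", "male", "unbiased"], 9)})
        fit = features.regress_timing_on_bias(timing, de, mode="categorical")
        slopes = [v for k, v in fit.params.items() if k != "Intercept"]
        assert np.allclose(slopes, 0.0, atol=1e-12)

    def test_planted_slope_within_3se(self):
        rng = np.random.default_rng(1)
        n = 1000
        log2fc = rng.normal(0, 1, n)
        timing = pd.Series(0.3 * log2fc + rng.normal(0, 0.05, n),
                           index=[f"G{i}" for i in range(n)])
        de = pd.DataFrame({"gene_id": timing.index, "log2fc": log2fc})
        fit = features.regress_timing_on_bias(timing, de)
        assert abs(fit.params["log2fc"] - 0.3) <= 3 * fit.bse["log2fc"]

    def test_constant_predictor_rejected(self):
        timing = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("ABCD"))
        de = pd.DataFrame({"gene_id": list("ABCD"), "log2fc": [1.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            features.regress_timing_on_bias(timing, de)
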