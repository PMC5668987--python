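import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xbias import escape, synthetic


def sites_from_ratios(sample_id, gene_ratios, coverage=1000):
    """Build a site table realizing the given per-(gene, site) ratios."""
    rows = []
    pos = 1
    for gene, ratios in gene_ratios.items():
        for r in np.atleast_1d(ratios):
            rows.append((sample_id, "chrX", pos, gene,
                         int(round(r * coverage)), coverage))
            pos += 1
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "gene_id", "major_count", "total_count"])


class TestClonalityNull:
    def test_degenerate_spread_floored(self):
        sites = sites_from_ratios("S1", {"A": [0.9], "B": [0.9], "C": [0.9]})
        null = escape.fit_clonality_null(sites, ["A", "B", "C"], "S1",
                                         min_null_obs=3)
        assert null.mu == pytest.approx(0.9)
        assert null.sigma == escape.DEFAULT_SIGMA_MIN

    def test_two_point_sd(self):
        sites = sites_from_ratios("S1", {"A": [0.8], "B": [1.0]})
        null = escape.fit_clonality_null(sites, ["A", "B"], "S1", min_null_obs=2)
        assert null.mu == pytest.approx(0.9)
        assert null.sigma == pytest.approx(np.std([0.8, 1.0], ddof=1), abs=1e-12)
        assert null.sigma == pytest.approx(0.1414, abs=5e-4)

    def test_too_few_observations_unusable(self):
        sites = sites_from_ratios("S1", {"A": [0.9]})
        null = escape.fit_clonality_null(sites, ["A"], "S1", min_null_obs=5)
        assert not null.usable

    def test_monoclonal_sample_recovers_theta(self):
        # theta = 0.95, coverage 1000, 50 silent single-site genes
        spec = synthetic.CohortSpec(
            n_samples=1, n_silent_genes=50, n_escape_genes=0,
            sites_per_gene=1.0, coverage_mean=1000, fail_fraction=0.0,
            clonality_alpha=1e6, clonality_beta=1e6 / 9, seed=11)
        sites, truth = synthetic.simulate_cohort(spec)
        assert truth.samples["theta"].iloc[0] == pytest.approx(0.95, abs=1e-3)
        null = escape.fit_clonality_null(
            sites, truth.genes["gene_id"].tolist(), "S0001")
        assert null.mu == pytest.approx(0.95, abs=0.01)


class TestGeneTest:
    def make_null(self, mu=0.9, sigma=0.05):
        return escape.ClonalityNull("S1", mu, sigma, 50, True)

    def test_null_centered_gene(self):
        sites = sites_from_ratios("S1", {"G": [0.9]})
        call = escape.test_gene("S1", "G", sites, self.make_null())
        assert call["z"] == pytest.approx(0.0)
        assert call["p"] == pytest.approx(0.5)
        assert not call["escape_flag"]

    def test_strong_escape(self):
        sites = sites_from_ratios("S1", {"G": [0.5]})
        call = escape.test_gene("S1", "G", sites, self.make_null())
        assert call["z"] == pytest.approx(-8.0)
        assert call["p"] == pytest.approx(stats.norm.cdf(-8), rel=1e-10)
        assert call["p"] == pytest.approx(6.22e-16, rel=1e-2)
        assert call["escape_flag"]

    def test_one_sigma_not_escape(self):
        sites = sites_from_ratios("S1", {"G": [0.85]})
        call = escape.test_gene("S1", "G", sites, self.make_null())
        assert call["z"] == pytest.approx(-1.0)
        assert call["p"] == pytest.approx(stats.norm.cdf(-1), rel=1e-10)
        assert call["p"] == pytest.approx(0.159, abs=1e-3)
        assert not call["escape_flag"]

    def test_unusable_null_no_call(self):
        sites = sites_from_ratios("S1", {"G": [0.5]})
        null = escape.ClonalityNull("S1", float("nan"), float("nan"), 2, False)
        assert escape.test_gene("S1", "G", sites, null) is None

    def test_coverage_weighted_aggregation(self):
        sites = pd.DataFrame({
            "sample_id": ["S1", "S1"], "chrom": ["chrX"] * 2, "pos": [1, 2],
            "gene_id": ["G", "G"], "major_count": [90, 30],
            "total_count": [100, 50]})
        call = escape.test_gene("S1", "G", sites, self.make_null())
        assert call["ratio"] == pytest.approx(120 / 150)
        unweighted = escape.test_gene("S1", "G", sites, self.make_null(),
                                      weighted=False)
        assert unweighted["ratio"] == pytest.approx((0.9 + 0.6) / 2)

    def test_monotone_in_ratio(self):
        # lowering the aggregated ratio never flips escape -> silent
        null = self.make_null()
        flags = []
        for r in np.linspace(0.95, 0.5, 40):
            sites = sites_from_ratios("S1", {"G": [r]})
            flags.append(escape.test_gene("S1", "G", sites, null)["escape_flag"])
        first_escape = flags.index(True)
        assert all(flags[first_escape:])


class TestAggregatePopulation:
    def make_calls(self, n_escape, n_total, gene="G"):
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n_total)],
            "gene_id": gene,
            "escape_flag": [i < n_escape for i in range(n_total)]})

    def test_above_cutoff_is_escape(self):
        out = escape.aggregate_population(self.make_calls(4, 10))
        assert out.loc[0, "population_call"] == "escape"

    def test_strict_inequality_boundary(self):
        out = escape.aggregate_population(self.make_calls(3, 10))
        assert out.loc[0, "frac_escape"] == pytest.approx(0.30)
        assert out.loc[0, "population_call"] == "silent"

    def test_insufficient_data(self):
        out = escape.aggregate_population(self.make_calls(4, 4))
        assert out.loc[0, "population_call"] == "insufficient_data"


class TestRoc:
    def test_perfect_separation(self):
        frac = pd.Series({"E1": 0.9, "E2": 0.9, "S1": 0.0, "S2": 0.0})
        roc = escape.roc_calibrate(frac, ["E1", "E2"], ["S1", "S2"])
        assert roc.auc == pytest.approx(1.0)

    def test_single_cutoff_grid(self):
        frac = pd.Series({"E": 0.4, "S": 0.2})
        roc = escape.roc_calibrate(frac, ["E"], ["S"], grid=np.array([0.3]))
        row = roc.table.iloc[0]
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0
        assert roc.chosen_cutoff == pytest.approx(0.3)

    def test_empty_known_list_errors(self):
        frac = pd.Series({"E": 0.4})
        with pytest.raises(escape.InsufficientDataError):
            escape.roc_calibrate(frac, ["E"], ["MISSING"])

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(3)
        esc = [f"E{i}" for i in range(40)]
        sil = [f"S{i}" for i in range(40)]
        frac = pd.Series(
            np.concatenate([rng.beta(6, 2, 40), rng.beta(2, 6, 40)]),
            index=esc + sil)
        roc = escape.roc_calibrate(frac, esc, sil,
                                   grid=np.linspace(0, 1, 2001))
        from sklearn.metrics import roc_auc_score
        labels = [0] * 40 + [1] * 40  # positive class = known silent
        expected = roc_auc_score(labels, -frac.to_numpy())
        assert roc.auc == pytest.approx(expected, abs=1e-3)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        esc = [f"E{i}" for i in range(30)]
        sil = [f"S{i}" for i in range(30)]
        values = np.concatenate([rng.beta(5, 2, 30), rng.beta(2, 5, 30)])
        frac = pd.Series(values, index=esc + sil)
        grid = np.linspace(0, 1, 4001)
        base = escape.roc_calibrate(frac, esc, sil, grid=grid).auc
        transformed = escape.roc_calibrate(frac ** 3, esc, sil, grid=grid).auc
        assert transformed == pytest.approx(base, abs=1e-9)


class TestCorrelation:
    def test_exact_linear(self):
        summ = pd.DataFrame({"gene_id": list("ABCDE"),
                             "frac_escape": [0.1, 0.2, 0.3, 0.4, 0.5]})
        de = pd.DataFrame({"gene_id": list("ABCDE"),
                           "log2fc": [1, 2, 3, 4, 5]})
        report = escape.correlate_escape_with_bias(summ, de)
        assert report.r == pytest.approx(1.0)
        de["log2fc"] = -de["log2fc"]
        assert escape.correlate_escape_with_bias(summ, de).r == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        summ = pd.DataFrame({"gene_id": ["A", "B"], "frac_escape": [0.1, 0.2]})
        de = pd.DataFrame({"gene_id": ["A", "B"], "log2fc": [1.0, 2.0]})
        with pytest.raises(escape.InsufficientDataError):
            escape.correlate_escape_with_bias(summ, de)
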