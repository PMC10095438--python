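import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtmkit import dmr, eqtm, expression, methylation, simulate


class TestMedian:
    def test_odd_even_and_single(self):
        beta = pd.DataFrame(
            {"S1": [0.2, 0.4, 0.9], "S2": [0.2, 0.4, 0.9]},
            index=["a", "b", "c"],
        )
        assert eqtm.dmr_median_methylation(beta, ["a", "b", "c"])["S1"] == pytest.approx(0.4)
        assert eqtm.dmr_median_methylation(beta, ["a", "b"])["S1"] == pytest.approx(0.3)
        assert eqtm.dmr_median_methylation(beta, ["c"])["S2"] == pytest.approx(0.9)

    def test_missing_member_errors(self):
        beta = pd.DataFrame({"S1": [0.2]}, index=["a"])
        with pytest.raises(ValueError, match="missing"):
            eqtm.dmr_median_methylation(beta, ["a", "zz"])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert eqtm.eqtm_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert eqtm.eqtm_correlation(x, -x) == pytest.approx(-1.0)

    def test_sum_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            x, y = rng.normal(size=(2, n))
            num = n * np.sum(x * y) - x.sum() * y.sum()
            den = np.sqrt(
                (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
            )
            assert eqtm.eqtm_correlation(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            eqtm.eqtm_correlation([1, 1, 1], [1, 2, 3])


class TestBootstrapCi:
    def test_collinear_family_degenerate_interval(self):
        x = np.linspace(0.1, 0.9, 10)
        lo, hi = eqtm.bootstrap_ci(x, 3 * x + 0.5, n_boot=500, seed=0)
        assert lo == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 30))
        assert eqtm.bootstrap_ci(x, y, 1000, seed=9) == eqtm.bootstrap_ci(x, y, 1000, seed=9)

    def test_interval_brackets_r_on_clean_data(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=63)
        y = 0.5 * x + rng.normal(size=63)
        r = eqtm.eqtm_correlation(x, y)
        lo, hi = eqtm.bootstrap_ci(x, y, 2000, seed=1)
        assert -1 <= lo <= r <= hi <= 1

    def test_width_shrinks_with_n(self):
        """Average CI width decreases over n ∈ {20, 63, 200}."""
        rng = np.random.default_rng(13)
        widths = []
        for n in (20, 63, 200):
            w = []
            for _ in range(30):
                x = rng.normal(size=n)
                y = 0.5 * x + rng.normal(size=n)
                lo, hi = eqtm.bootstrap_ci(x, y, 1000, seed=rng)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_mostly_degenerate_errors(self):
        x = np.array([1.0, 1.0, 1.0])
        y = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            eqtm.bootstrap_ci(x, y, 200, seed=0)


class TestResamplingPvalue:
    def test_add_one_floor(self):
        x = np.linspace(0, 1, 63)
        p = eqtm.resampling_pvalue(x, 2 * x, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_exhaustive_enumeration_n5(self):
        """Estimator converges to the full 120-permutation tail probability."""
        rng = np.random.default_rng(23)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r_obs = abs(eqtm.eqtm_correlation(x, y))
        hits = sum(
            abs(np.corrcoef(x, np.array(perm))[0, 1]) >= r_obs - 1e-12
            for perm in itertools.permutations(y)
        )
        p_enum = hits / 120
        p_est = eqtm.resampling_pvalue(x, y, n_perm=40000, seed=1)
        assert p_est == pytest.approx(p_enum, abs=0.02)

    def test_uniform_under_null(self):
        """Null p-values pass a KS test against Uniform(0,1) at α = 0.01."""
        rng = np.random.default_rng(99)
        ps = [
            eqtm.resampling_pvalue(rng.normal(size=30), rng.normal(size=30),
                                   n_perm=999, seed=rng)
            for _ in range(500)
        ]
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 20))
        assert eqtm.resampling_pvalue(x, y, 999, seed=4) == eqtm.resampling_pvalue(
            x, y, 999, seed=4
        )


class TestGroupCorrelations:
    def test_shared_linear_law(self):
        x = np.linspace(0, 1, 12)
        y = 2 * x
        groups = np.array(["case"] * 6 + ["control"] * 6)
        r_case, r_control = eqtm.group_correlations(x, y, groups)
        assert r_case == pytest.approx(1.0)
        assert r_control == pytest.approx(1.0)

    def test_case_only_coupling(self):
        rng = np.random.default_rng(3)
        n_case, n_ctrl = 30, 30
        x = rng.normal(size=n_case + n_ctrl)
        y = np.empty_like(x)
        y[:n_case] = 2 * x[:n_case] + 0.1 * rng.normal(size=n_case)
        y[n_case:] = rng.normal(size=n_ctrl)
        groups = np.array(["case"] * n_case + ["control"] * n_ctrl)
        r_case, r_control = eqtm.group_correlations(x, y, groups)
        assert abs(r_case) > 0.9
        assert abs(r_control) < 0.4

    def test_small_group_sentinel(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = x.copy()
        groups = np.array(["case", "case", "control", "control", "control"])
        r_case, r_control = eqtm.group_correlations(x, y, groups)
        assert np.isnan(r_case)
        assert r_control == pytest.approx(1.0)


class TestClassification:
    def test_direction_labels(self):
        assert eqtm.classify_expression_direction(0.5, 0.0) == "Overexpression"
        assert eqtm.classify_expression_direction(-0.5, 0.0) == "Underexpression"
        assert eqtm.classify_expression_direction(0.0, 0.3) == "Overexpression"
        assert eqtm.classify_expression_direction(0.0, 0.0) == "none"


def _run_pipeline(cohort, config=None):
    dmps = methylation.fit_dmps(cohort.beta, cohort.samples)
    dmrs = dmr.call_dmrs(dmps, cohort.cpg_annotation, 0.1)
    config = config or eqtm.EqtmConfig(n_boot=2000, n_perm=2000, seed=1)
    res = eqtm.run_eqtm_analysis(
        cohort.beta, cohort.counts, cohort.samples, dmrs,
        cohort.gene_models, cohort.cpg_annotation, config,
    )
    return dmrs, res


class TestRunEqtmAnalysis:
    def test_planted_pairs_recovered_with_labels(self, small_cohort):
        dmrs, res = _run_pipeline(small_cohort)
        truth = {p["region_key"]: p for p in small_cohort.truth.eqtm_pairs}
        found = 0
        for region_id, row in res.iterrows():
            if region_id in truth and truth[region_id]["gene_id"] == row["gene_id"]:
                found += 1
                assert np.sign(row["r"]) == np.sign(truth[region_id]["rho"])
        assert found >= len(truth) - 2  # regions can be truncated by FDR noise

    def test_hypo_negative_r_means_case_overexpression(self, small_cohort):
        _, res = _run_pipeline(small_cohort)
        hypo_neg = res[(res["dmr_direction"] == "Hypo-methylated") & (res["r"] < -0.2)
                       & res["significant"]]
        assert len(hypo_neg) > 0
        assert (hypo_neg["expression_direction"] == "Overexpression").all()

    def test_self_consistency_of_reported_r(self, small_cohort):
        dmrs, res = _run_pipeline(small_cohort)
        kept = expression.filter_expressed(small_cohort.counts)
        norm, _ = expression.normalize_counts(kept)
        log_expr = expression.log_transform(norm)
        for region_id, row in res.iterrows():
            members = dmrs.loc[region_id, "member_cpgs"].split(",")
            med = eqtm.dmr_median_methylation(small_cohort.beta, members)
            r = eqtm.eqtm_correlation(med, log_expr.loc[row["gene_id"]])
            assert row["r"] == pytest.approx(r, abs=1e-12)
            assert row["ci_low"] - 1e-9 <= row["r"] <= row["ci_high"] + 1e-9

    def test_empty_dmr_table(self, small_cohort):
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpgs", "member_cpgs", "genes",
                     "mean_delta_beta", "direction", "mixed_direction",
                     "stouffer_z", "stouffer_p"],
            index=pd.Index([], name="region_id"),
        )
        res = eqtm.run_eqtm_analysis(
            small_cohort.beta, small_cohort.counts, small_cohort.samples,
            empty, small_cohort.gene_models, small_cohort.cpg_annotation,
            eqtm.EqtmConfig(n_boot=100, n_perm=100),
        )
        assert len(res) == 0

    def test_deterministic_given_seed(self, small_cohort):
        _, res1 = _run_pipeline(small_cohort)
        _, res2 = _run_pipeline(small_cohort)
        pd.testing.assert_frame_equal(res1, res2)


class TestMatchCis:
    def _dmrs(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "start": [100, 5000, 9000],
             "end": [200, 5100, 9100], "genes": ["G1", "G2", ""]},
            index=pd.Index(["r1", "r2", "r3"], name="region_id"),
        )

    def _genes(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "tss": [150, 5050, 9500],
             "start": [150, 5050, 9500], "end": [1000, 6000, 10000],
             "strand": ["+", "+", "+"],
             "first_exon_start": [150, 5050, 9500],
             "first_exon_end": [250, 5150, 9600]},
            index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        )

    def test_expressed_gene_paired(self):
        pairs, drops = eqtm.match_cis(self._dmrs().iloc[:1], self._genes(), {"G1"})
        assert pairs == [("r1", "G1", False)]

    def test_unexpressed_gene_drop_logged(self):
        pairs, drops = eqtm.match_cis(self._dmrs().iloc[1:2], self._genes(), {"G1"})
        assert pairs == []
        assert drops[0]["reason"] == "not expressed"

    def test_multi_gene_fanout(self):
        dmrs = self._dmrs().iloc[:1].copy()
        dmrs["genes"] = "G1,G2"
        pairs, _ = eqtm.match_cis(dmrs, self._genes(), {"G1", "G2"})
        assert {(p[0], p[1]) for p in pairs} == {("r1", "G1"), ("r1", "G2")}

    def test_intergenic_nearest_tss_flagged(self):
        pairs, _ = eqtm.match_cis(self._dmrs().iloc[2:], self._genes(), {"G3"})
        assert pairs == [("r3", "G3", True)]

    def test_intergenic_out_of_window_dropped(self):
        pairs, drops = eqtm.match_cis(
            self._dmrs().iloc[2:], self._genes(), {"G3"}, nearest_tss_window=100
        )
        assert pairs == []
        assert drops[0]["reason"] == "no gene in range"
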