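"""Calibration statistics, Monte-Carlo null machinery and the unified test."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest

from mroc import (
    NullDistribution,
    PredictionSample,
    component_pvalues,
    mean_calibration_stat,
    roc_equality_stat,
    run_calibration_test,
    simulate_null_distribution,
    unified_pvalue,
)

from conftest import enumerated_mean_abs_binom_dev, grid_abs_diff


class TestStatistics:
    @pytest.mark.parametrize(
        "outcomes, risks, expected",
        [
            ((1, 0), (0.5, 0.5), 0.0),
            ((1, 0, 0), (0.5, 0.5, 0.5), 1.0 / 6.0),
            ((1, 0, 1), (1.0, 0.0, 1.0), 0.0),  # perfect binary predictions
        ],
    )
    def test_mean_calibration_hand_values(self, outcomes, risks, expected):
        s = PredictionSample(np.array(risks), np.array(outcomes))
        assert mean_calibration_stat(s) == pytest.approx(expected, abs=1e-15)

    def test_mean_calibration_permutation_invariant(self, rng):
        r = rng.random(30)
        y = (rng.random(30) < r).astype(float)
        base = mean_calibration_stat(PredictionSample(r, y))
        perm = rng.permutation(30)
        assert mean_calibration_stat(PredictionSample(r[perm], y[perm])) == base

    def test_roc_equality_matches_grid_oracle(self):
        from mroc import empirical_roc, mroc

        s = PredictionSample(np.array([0.2, 0.8]), np.array([0.0, 1.0]))
        b = roc_equality_stat(s)
        assert b == pytest.approx(grid_abs_diff(empirical_roc(s), mroc(s.risks)), abs=1e-6)
        assert b == pytest.approx(0.2, abs=1e-12)  # hand integration of the two curves

    def test_roc_equality_invariant_to_relabeling(self, rng):
        r = rng.random(40)
        y = (rng.random(40) < r).astype(float)
        if not 0 < y.sum() < 40:
            y[0], y[-1] = 1.0, 0.0
        base = roc_equality_stat(PredictionSample(r, y))
        perm = rng.permutation(40)
        assert roc_equality_stat(PredictionSample(r[perm], y[perm])) == pytest.approx(base, abs=1e-14)

    def test_roc_equality_small_for_large_calibrated_samples(self):
        """Bn < 0.02 with high probability at n = 10,000 under the null."""
        hits = 0
        for j in range(40):
            rng = np.random.default_rng([77, j])
            pi = expit(rng.standard_normal(10_000))
            y = (rng.random(10_000) < pi).astype(float)
            hits += roc_equality_stat(PredictionSample(pi, y)) < 0.02
        assert hits >= 38  # >= 95%


class TestNullDistribution:
    def test_determinism_bit_identical(self, rng):
        risks = rng.random(60)
        nd1 = simulate_null_distribution(risks, M=400, seed=12)
        nd2 = simulate_null_distribution(risks, M=400, seed=12)
        np.testing.assert_array_equal(nd1.a_samples, nd2.a_samples)
        np.testing.assert_array_equal(nd1.b_samples, nd2.b_samples)
        assert nd1.n_degenerate == nd2.n_degenerate

    def test_small_m_rejected(self, rng):
        with pytest.raises(ValueError, match="M >= 100"):
            simulate_null_distribution(rng.random(20), M=50, seed=0)

    def test_constant_risk_null_matches_exact_enumeration(self):
        """Mean of An* under pi = 1/2 equals E|Binomial(n,1/2)/n - 1/2|.

        The enumeration conditions on both classes appearing, matching the
        redraw policy for degenerate outcome vectors (common at n = 8).
        """
        n, M = 8, 40_000
        with pytest.warns(RuntimeWarning, match="degenerate"):
            nd = simulate_null_distribution(np.full(n, 0.5), M=M, seed=3)
        exact = enumerated_mean_abs_binom_dev(n)
        se = nd.a_samples.std(ddof=1) / np.sqrt(M)
        assert nd.a_samples.mean() == pytest.approx(exact, abs=4 * se)

    def test_degenerate_draws_redrawn_and_counted(self):
        # extreme risks at tiny n make all-zero outcome vectors common
        with pytest.warns(RuntimeWarning, match="degenerate"):
            nd = simulate_null_distribution(np.full(3, 0.05), M=200, seed=1)
        assert nd.n_degenerate > 0
        assert nd.a_samples.shape == (200,)

    def test_audit_tsv_export(self, rng, tmp_path):
        nd = simulate_null_distribution(rng.random(20), M=120, seed=5)
        path = tmp_path / "null.tsv"
        nd.to_tsv(path)
        data = np.loadtxt(path, skiprows=1)
        np.testing.assert_array_equal(data[:, 0], nd.a_samples)


class TestComponentPValues:
    def _nd(self, a, b):
        a = np.asarray(a, dtype=float)
        return NullDistribution(a, np.asarray(b, dtype=float), m=a.size, seed=0)

    def test_observed_below_all_nulls_gives_one(self, rng):
        nd = self._nd(rng.random(500) * 0.5 + 0.4, rng.random(500) * 0.5 + 0.4)
        p_a, p_b = component_pvalues(nd, 0.0, 0.0)
        assert p_a == 1.0 and p_b == 1.0

    def test_observed_above_all_nulls_hits_smoothing_floor(self, rng):
        nd = self._nd(rng.random(999) * 0.5, rng.random(999) * 0.5)
        p_a, p_b = component_pvalues(nd, 0.99, 0.99)
        assert p_a == pytest.approx(1.0 / 1000.0)
        assert p_b == pytest.approx(1.0 / 1000.0)

    def test_observed_at_median_gives_half(self, rng):
        a = rng.random(9999)
        nd = self._nd(a, a)
        p_a, _ = component_pvalues(nd, float(np.median(a)), 0.0)
        assert p_a == pytest.approx(0.5, abs=0.01)


class TestUnifiedPValue:
    def test_null_pvalues_of_one_give_unified_one(self, rng):
        nd = NullDistribution(rng.random(1000) * 0.9, rng.random(1000) * 0.9, m=1000, seed=0)
        res = unified_pvalue(nd, 1.0, 1.0)
        assert res.u_stat == 0.0
        assert res.p_unified == 1.0

    def test_independent_continuous_nulls_recover_fisher_chi2_4(self):
        """With independence imposed, moment matching gives df~4, scale~1."""
        rng = np.random.default_rng(8)
        nd = NullDistribution(rng.random(50_000) * 0.9, rng.random(50_000) * 0.9,
                              m=50_000, seed=0)
        res = unified_pvalue(nd, 0.5, 0.5)
        assert res.df_matched == pytest.approx(4.0, abs=0.15)
        assert res.scale_matched == pytest.approx(1.0, abs=0.05)

    def test_u_monotone_decreasing_in_each_component(self, rng):
        nd = NullDistribution(rng.random(500) * 0.9, rng.random(500) * 0.9, m=500, seed=0)
        u_base = unified_pvalue(nd, 0.5, 0.5)
        assert unified_pvalue(nd, 0.1, 0.5).u_stat > u_base.u_stat
        assert unified_pvalue(nd, 0.5, 0.1).u_stat > u_base.u_stat
        assert unified_pvalue(nd, 0.9, 0.9).u_stat < u_base.u_stat

    def test_invalid_pvalues_rejected(self, rng):
        nd = NullDistribution(rng.random(200) * 0.9, rng.random(200) * 0.9, m=200, seed=0)
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            unified_pvalue(nd, 0.0, 0.5)


class TestRunCalibrationTest:
    def test_determinism(self, rng):
        r = rng.random(80)
        y = (rng.random(80) < r).astype(float)
        s = PredictionSample(r, y)
        res1 = run_calibration_test(s, M=200, seed=9)
        res2 = run_calibration_test(s, M=200, seed=9)
        assert res1 == res2

    def test_calibrated_large_sample_not_rejected(self):
        rng = np.random.default_rng(21)
        pi = expit(rng.standard_normal(4000))
        y = (rng.random(4000) < pi).astype(float)
        res = run_calibration_test(PredictionSample(pi, y), M=2000, seed=2)
        assert res.p_unified > 0.05

    def test_severe_miscalibration_rejected(self):
        """pi* = expit(3X) against truth expit(X): rejected in >=95% of runs."""
        rejections = 0
        for j in range(100):
            rng = np.random.default_rng([31, j])
            x = rng.standard_normal(1000)
            y = (rng.random(1000) < expit(x)).astype(float)
            res = run_calibration_test(PredictionSample(expit(3 * x), y), M=300, seed=j)
            rejections += res.p_unified < 0.05
        assert rejections >= 95

    def test_json_round_trip(self, rng, tmp_path):
        import json

        r = rng.random(50)
        y = (rng.random(50) < r).astype(float)
        res = run_calibration_test(PredictionSample(r, y), M=150, seed=4)
        path = tmp_path / "result.json"
        res.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["p_unified"] == res.p_unified
        assert loaded["m"] == 150


def test_component_and_unified_pvalues_uniform_under_null():
    """Under H0 the p-values are (approximately) Uniform(0, 1)."""
    p_a, p_b, p_u = [], [], []
    for j in range(400):
        rng = np.random.default_rng([42, j])
        pi = expit(rng.standard_normal(100))
        y = (rng.random(100) < pi).astype(float)
        if not 0 < y.sum() < 100:
            continue
        res = run_calibration_test(PredictionSample(pi, y), M=500, seed=j)
        p_a.append(res.p_a)
        p_b.append(res.p_b)
        p_u.append(res.p_unified)
    for name, p in (("p_a", p_a), ("p_b", p_b), ("p_unified", p_u)):
        stat, pval = kstest(p, "uniform")
        assert pval > 0.01, f"{name} fails uniformity: KS p = {pval:.4f}"
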