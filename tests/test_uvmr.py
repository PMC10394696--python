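"""Univariable MR estimators: Wald ratios, IVW, Egger, median, mode, LOO."""

import numpy as np
import pytest

from mrmediate.uvmr import (
    ivw,
    leave_one_out,
    mr_egger,
    wald_ratios,
    weighted_median,
    weighted_mode,
)

from conftest import make_hs, random_hs


class TestWaldRatios:
    def test_arithmetic(self):
        r = wald_ratios(make_hs([0.1], [0.01], [0.02], [0.01]))
        assert r.theta[0] == pytest.approx(0.2)
        assert r.se_theta[0] == pytest.approx(0.1)
        assert r.weight[0] == pytest.approx(100.0)

    def test_zero_outcome_gives_zero_ratio(self):
        r = wald_ratios(make_hs([0.1], [0.01], [0.0], [0.01]))
        assert r.theta[0] == 0.0

    def test_scale_invariance(self):
        r1 = wald_ratios(make_hs([0.1], [0.01], [0.02], [0.01]))
        r2 = wald_ratios(make_hs([0.2], [0.01], [0.04], [0.01]))
        assert r1.theta[0] == pytest.approx(r2.theta[0])

    def test_zero_exposure_effect_dropped_with_reason(self):
        r = wald_ratios(make_hs([0.0, 0.1], [0.01, 0.01], [0.1, 0.02], [0.01, 0.01]))
        assert len(r) == 1
        assert r.dropped == [("rs1", "zero exposure effect")]


class TestIVW:
    def test_degenerate_agreement(self):
        hs = make_hs([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.01] * 3)
        est, q = ivw(hs)
        assert est.beta == pytest.approx(0.2)
        assert q.q == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_two_snps(self):
        # equal weights, theta = 0.1 and 0.3 -> beta 0.2, Q = 2 w (0.1)^2
        hs = make_hs([1.0, 1.0], [0.1, 0.1], [0.1, 0.3], [1.0, 1.0])
        est, q = ivw(hs, model="fixed")
        assert est.beta == pytest.approx(0.2)
        assert q.q == pytest.approx(2 * 1.0 * 0.01)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_insufficient_instruments(self):
        with pytest.raises(ValueError, match="insufficient"):
            ivw(make_hs([0.1], [0.01], [0.02], [0.01]))

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            hs = random_hs(rng, true_effect=0.1)
            fixed, _ = ivw(hs, model="fixed")
            random_, _ = ivw(hs, model="random")
            assert random_.se >= fixed.se - 1e-15
            assert random_.beta == pytest.approx(fixed.beta)

    def test_unbiased_with_nominal_coverage(self, rng):
        """1,000 replicates at true effect ln(1.21): mean within 0.01, ~95% CI.

        Strong instruments (F of a few hundred), the regime in which the
        first-order Wald-ratio SE is accurate.
        """
        true = np.log(1.21)
        m, reps = 50, 1000
        est, cover = [], 0
        for _ in range(reps):
            sx = rng.uniform(0.005, 0.015, m)
            sy = rng.uniform(0.01, 0.02, m)
            bx_true = rng.choice([-1, 1], m) * rng.uniform(12, 20, m) * sx
            hs = make_hs(
                bx_true + rng.standard_normal(m) * sx, sx,
                true * bx_true + rng.standard_normal(m) * sy, sy,
            )
            e, _ = ivw(hs)
            est.append(e.beta)
            cover += e.ci_low <= true <= e.ci_high
        assert abs(np.mean(est) - true) < 0.01
        assert 0.93 <= cover / reps <= 0.97

    def test_q_invariant_to_order(self, rng):
        hs = random_hs(rng, m=8, true_effect=0.1)
        perm = rng.permutation(8)
        _, q1 = ivw(hs)
        _, q2 = ivw(hs.subset(perm))
        assert q1.q == pytest.approx(q2.q)


class TestEgger:
    def test_exact_linear_fit(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = 0.05 + 0.2 * x
        res = mr_egger(make_hs(x, [0.01] * 4, y, [0.01] * 4))
        assert res.slope.beta == pytest.approx(0.2, abs=1e-12)
        assert res.intercept.value == pytest.approx(0.05, abs=1e-12)

    def test_orientation_invariance(self, rng):
        """Flipping SNP orientations (both betas) leaves the fit unchanged."""
        hs = random_hs(rng, m=10, true_effect=0.2)
        sign = rng.choice([-1.0, 1.0], 10)
        flipped = make_hs(hs.beta_exposure * sign, hs.se_exposure,
                          hs.beta_outcome * sign, hs.se_outcome)
        r1, r2 = mr_egger(hs), mr_egger(flipped)
        assert r1.slope.beta == pytest.approx(r2.slope.beta)
        assert r1.intercept.value == pytest.approx(r2.intercept.value)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError, match="insufficient"):
            mr_egger(make_hs([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.01] * 2))

    def test_detects_directional_pleiotropy(self, rng):
        """Intercept test has power against mean pleiotropic effect 0.02."""
        reps, hits = 200, 0
        for _ in range(reps):
            m = 30
            sx = np.full(m, 0.02)
            sy = np.full(m, 0.01)
            bx_true = rng.uniform(5, 9, m) * sx  # oriented positive (InSIDE holds)
            pleio = rng.normal(0.02, 0.01, m)
            bx = bx_true + rng.standard_normal(m) * sx
            by = 0.1 * bx_true + pleio + rng.standard_normal(m) * sy
            res = mr_egger(make_hs(bx, sx, by, sy))
            hits += res.intercept.pval < 0.05
        assert hits / reps > 0.5  # far above the 5% type-I rate


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        hs = make_hs([1.0] * 3, [0.1] * 3, [0.1, 0.2, 0.3], [1.0] * 3)
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_heavy_weight_dominates(self):
        # weights {1, 1, 100}: interpolated estimate 0.2 + 0.1 * (0.5 - 1.5/102)
        # / (50.5/102) = 0.29802
        hs = make_hs([1.0, 1.0, 10.0], [0.1] * 3, [0.1, 0.2, 3.0], [1.0, 1.0, 1.0])
        est = weighted_median(hs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2980198, rel=1e-5)

    def test_robust_to_30pct_invalid_instruments(self, rng):
        """Median bias stays below IVW bias under large directional pleiotropy."""
        true, reps = np.log(1.21), 300
        med_err, ivw_err = [], []
        for _ in range(reps):
            m = 30
            sx = np.full(m, 0.02)
            sy = np.full(m, 0.01)
            bx_true = rng.uniform(5, 9, m) * sx  # oriented so pleiotropy is directional
            pleio = np.where(np.arange(m) < m * 0.3, 0.05, 0.0)
            bx = bx_true + rng.standard_normal(m) * sx
            by = true * bx_true + pleio + rng.standard_normal(m) * sy
            hs = make_hs(bx, sx, by, sy)
            med_err.append(weighted_median(hs, n_boot=50, seed=2).beta - true)
            ivw_err.append(ivw(hs)[0].beta - true)
        assert abs(np.mean(med_err)) < abs(np.mean(ivw_err))

    def test_bootstrap_reproducible(self, rng):
        hs = random_hs(rng, m=8, true_effect=0.1)
        a = weighted_median(hs, n_boot=300, seed=7)
        b = weighted_median(hs, n_boot=300, seed=7)
        c = weighted_median(hs, n_boot=300, seed=8)
        assert a == b
        assert a.se != c.se


class TestWeightedMode:
    def test_zero_spread_returns_common_value(self):
        hs = make_hs([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.01] * 3)
        est = weighted_mode(hs, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_mode_ignores_single_outlier(self):
        hs = make_hs([1.0] * 4, [0.05] * 4, [0.2, 0.2, 0.2, 0.9], [0.05] * 4)
        est = weighted_mode(hs, n_boot=100, seed=1)
        assert abs(est.beta - 0.2) < 0.05  # near the cluster, not the mean 0.375

    def test_reflection_symmetry(self, rng):
        hs = random_hs(rng, m=9, true_effect=0.15)
        neg = make_hs(hs.beta_exposure, hs.se_exposure, -hs.beta_outcome,
                      hs.se_outcome)
        a = weighted_mode(hs, n_boot=100, seed=3)
        b = weighted_mode(neg, n_boot=100, seed=3)
        assert a.beta == pytest.approx(-b.beta, rel=1e-6)

    def test_bootstrap_reproducible(self, rng):
        hs = random_hs(rng, m=8, true_effect=0.1)
        assert weighted_mode(hs, n_boot=200, seed=5) == weighted_mode(
            hs, n_boot=200, seed=5
        )


class TestLeaveOneOut:
    def test_length_and_identical_snps(self):
        hs = make_hs([0.1] * 5, [0.01] * 5, [0.02] * 5, [0.01] * 5)
        loo = leave_one_out(hs)
        assert len(loo) == 5
        full, _ = ivw(hs)
        for _, est in loo:
            assert est.beta == pytest.approx(full.beta)

    def test_removing_outlier_moves_estimate_toward_truth(self):
        bx = np.array([0.1, 0.12, 0.15, 0.11, 0.13])
        by = 0.2 * bx
        by[-1] += 0.15  # contaminated SNP
        hs = make_hs(bx, [0.01] * 5, by, [0.01] * 5)
        loo = dict(leave_one_out(hs))
        full, _ = ivw(hs)
        assert abs(loo["rs5"].beta - 0.2) < abs(full.beta - 0.2)
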