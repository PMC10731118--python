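import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkit import (
    ConfigurationError,
    DomainError,
    HarmonizedSet,
    InsufficientInstrumentsError,
    MREstimate,
    egger,
    ivw,
    scenario,
    simulate_two_sample,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from oracles import ivw_via_wls, weighted_median_reference, wls_normal_equations


def hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float) if sx is not None else np.full_like(bx, 0.01)
    return HarmonizedSet.from_arrays(bx, sx, np.asarray(by, float), np.asarray(sy, float))


class TestWald:
    def test_direct_ratio(self):
        e = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert e.theta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.1)
        assert e.ci_low < e.theta < e.ci_high

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).theta == 0.0

    def test_orientation_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.01)
        assert a.theta == b.theta and a.se == b.se

    def test_degenerate_instrument(self):
        with pytest.raises(DomainError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_identical_ratios_give_zero_q(self):
        est, q = ivw(hset([0.1, 0.2], [0.05, 0.10], [0.01, 0.01]))
        assert est.theta == pytest.approx(0.5)
        assert q.q == pytest.approx(0.0, abs=1e-25)

    def test_single_snp_reduces_to_wald(self):
        est, q = ivw(hset([0.1], [0.05], [0.02]))
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.theta == pytest.approx(w.theta) and est.se == pytest.approx(w.se)
        assert q.df == 0

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            j = int(rng.integers(2, 30))
            bx = rng.normal(0.1, 0.03, j)
            by = rng.normal(0.03, 0.02, j)
            sy = rng.uniform(0.005, 0.05, j)
            est, _ = ivw(hset(bx, by, sy))
            theta_o, se_o = ivw_via_wls(bx, by, sy)
            assert est.theta == pytest.approx(theta_o, abs=1e-12)
            assert est.se == pytest.approx(se_o, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data())
    def test_wls_equivalence_property(self, data):
        j = data.draw(st.integers(2, 15))
        bx = data.draw(
            st.lists(st.floats(0.01, 0.5), min_size=j, max_size=j).map(np.array)
        )
        by = data.draw(
            st.lists(st.floats(-0.2, 0.2), min_size=j, max_size=j).map(np.array)
        )
        sy = data.draw(
            st.lists(st.floats(0.001, 0.1), min_size=j, max_size=j).map(np.array)
        )
        est, _ = ivw(hset(bx, by, sy))
        theta_o, _ = ivw_via_wls(bx, by, sy)
        assert est.theta == pytest.approx(theta_o, abs=1e-10)

    def test_random_effects_inflates_only_under_heterogeneity(self):
        h_homog = hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01] * 3)
        f, _ = ivw(h_homog)
        r, _ = ivw(h_homog, effects="random_multiplicative")
        assert r.se == pytest.approx(f.se)  # floor at 1
        h_het = hset([0.1, 0.2, 0.3], [0.08, 0.01, 0.40], [0.01] * 3)
        f2, q2 = ivw(h_het)
        r2, _ = ivw(h_het, effects="random_multiplicative")
        assert r2.se == pytest.approx(f2.se * np.sqrt(q2.q / q2.df))
        assert r2.theta == f2.theta

    def test_q_invariant_to_order(self):
        rng = np.random.default_rng(4)
        bx, by, sy = rng.normal(0.1, 0.02, 8), rng.normal(0.05, 0.02, 8), rng.uniform(0.01, 0.02, 8)
        _, q1 = ivw(hset(bx, by, sy))
        p = rng.permutation(8)
        _, q2 = ivw(hset(bx[p], by[p], sy[p]))
        assert q1.q == pytest.approx(q2.q, rel=1e-12)

    def test_zero_beta_x_excluded(self):
        est, _ = ivw(hset([0.1, 0.0, 0.2], [0.05, 0.9, 0.1], [0.01] * 3))
        assert est.n_snps == 2
        assert est.theta == pytest.approx(0.5)

    def test_unknown_effects_model(self):
        with pytest.raises(ConfigurationError):
            ivw(hset([0.1, 0.2], [0.05, 0.1], [0.01] * 2), effects="dersimonian")


class TestEgger:
    def test_exact_fit_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        by = 0.01 + 0.3 * bx
        res = egger(hset(bx, by, [0.01] * 5))
        assert res.slope.theta == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.01, abs=1e-10)

    def test_matches_wls_oracle_with_intercept(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.02, 0.3, 25)
        by = rng.normal(0.01 + 0.2 * bx, 0.02)
        sy = rng.uniform(0.005, 0.05, 25)
        res = egger(hset(bx, by, sy))
        x = np.column_stack([np.ones_like(bx), bx])
        beta, cov = wls_normal_equations(x, by, 1.0 / sy**2)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope.theta == pytest.approx(beta[1], abs=1e-10)

    def test_reorientation_invariance(self):
        rng = np.random.default_rng(12)
        bx = rng.uniform(0.02, 0.3, 12)
        by = rng.normal(0.3 * bx, 0.02)
        sy = rng.uniform(0.01, 0.03, 12)
        res1 = egger(hset(bx, by, sy))
        flip = rng.random(12) < 0.5
        s = np.where(flip, -1.0, 1.0)
        res2 = egger(hset(bx * s, by * s, sy))
        assert res2.slope.theta == pytest.approx(res1.slope.theta, rel=1e-12)
        assert res2.intercept == pytest.approx(res1.intercept, rel=1e-12)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        study = simulate_two_sample(scenario("balanced_pleiotropy", seed=1))
        res = egger(study.harmonized())
        assert abs(res.intercept) < 3 * res.intercept_se

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.05, 0.1], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weight_ratios_equals_simple_median(self):
        est = weighted_median(hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.01] * 3), seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_all_equal_ratios_with_tiny_noise(self):
        est = weighted_median(
            hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [1e-8] * 3, sx=[1e-8] * 3),
            seed=1,
        )
        assert est.theta == pytest.approx(0.5)
        assert est.se < 1e-5  # bootstrap SE shrinks with the sampling noise

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            j = int(rng.integers(3, 40))
            bx = rng.uniform(0.02, 0.3, j)
            by = rng.normal(0.1 * bx, 0.02)
            sy = rng.uniform(0.005, 0.05, j)
            est = weighted_median(hset(bx, by, sy), n_boot=2, seed=1)
            ref = weighted_median_reference(by / bx, bx**2 / sy**2)
            assert est.theta == pytest.approx(ref, abs=1e-12)

    def test_requires_seed(self):
        with pytest.raises(ConfigurationError):
            weighted_median(hset([0.1] * 3, [0.05] * 3, [0.01] * 3))

    def test_robust_to_minority_directional_pleiotropy(self):
        study = simulate_two_sample(scenario("directional_pleiotropy", seed=1))
        h = study.harmonized()
        med = weighted_median(h, seed=2)
        est_ivw, _ = ivw(h)
        theta = study.truth.theta
        assert abs(med.theta - theta) < 3 * med.se
        assert abs(est_ivw.theta - theta) > 3 * est_ivw.se  # IVW is biased here


class TestWeightedMode:
    def test_all_ratios_identical(self):
        est = weighted_mode(hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01] * 3), seed=1)
        assert est.theta == pytest.approx(0.5)

    def test_majority_cluster_wins_over_mean(self):
        bx = np.full(10, 0.1)
        by = np.array([0.05] * 7 + [0.30] * 3)  # ratios 0.5 (7 SNPs) and 3.0 (3 SNPs)
        est = weighted_mode(hset(bx, by, [0.01] * 10), seed=3)
        ivw_est, _ = ivw(hset(bx, by, [0.01] * 10))
        assert abs(est.theta - 0.5) < 0.1
        assert ivw_est.theta > 1.0  # the mean is dragged by the outliers

    def test_invariant_to_duplication(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        by = np.array([0.05, 0.07, 0.11, 0.12])
        sy = np.array([0.01, 0.02, 0.01, 0.015])
        e1 = weighted_mode(hset(bx, by, sy), n_boot=2, seed=1)
        e2 = weighted_mode(
            hset(np.tile(bx, 2), np.tile(by, 2), np.tile(sy, 2)), n_boot=2, seed=1
        )
        # identical up to the J-dependent bandwidth and grid resolution
        assert e2.theta == pytest.approx(e1.theta, abs=0.02)

    def test_plurality_valid_contract(self):
        study = simulate_two_sample(scenario("inside_violation", seed=1))
        est = weighted_mode(study.harmonized(), seed=2)
        assert abs(est.theta - study.truth.theta) < 3 * est.se


class TestOddsRatio:
    def test_null_theta_gives_unit_or(self):
        e = MREstimate("ivw_fixed", 0.0, 0.1, -0.196, 0.196, 1.0, 5)
        orv, lo, hi = to_odds_ratio(e)
        assert orv == pytest.approx(1.0)
        assert lo < orv < hi

    def test_protective_effect_shape(self):
        # a strong protective estimate: OR ~ 0.10, CI ~ (0.01, 0.72)
        e = MREstimate("ivw_fixed", -2.303, 1.09, -4.6, -0.33, 0.02, 7)
        orv, lo, hi = to_odds_ratio(e)
        assert orv == pytest.approx(0.10, abs=0.005)
        assert lo == pytest.approx(0.01, abs=0.005)
        assert hi == pytest.approx(0.72, abs=0.005)

    def test_exp_preserves_ordering(self):
        e = MREstimate("ivw_fixed", 0.2, 0.1, 0.004, 0.396, 0.04, 3)
        orv, lo, hi = to_odds_ratio(e)
        assert lo < orv < hi


class TestNoiselessConsistency:
    def test_all_estimators_recover_theta_exactly(self):
        """With beta_y = theta * beta_x exactly, every estimator returns theta."""
        theta = 0.42
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3])
        by = theta * bx
        h = hset(bx, by, [0.01] * 6)
        est, q = ivw(h)
        assert est.theta == pytest.approx(theta, abs=1e-12)
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert egger(h).slope.theta == pytest.approx(theta, abs=1e-10)
        assert weighted_median(h, n_boot=2, seed=1).theta == pytest.approx(theta, abs=1e-12)
        assert weighted_mode(h, n_boot=2, seed=1).theta == pytest.approx(theta, abs=1e-3)
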