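"""Estimator correctness: worked examples, independent oracles, invariances."""

import numpy as np
import pytest
from scipy import stats

from mrkit import (EstimationError, SimulationConfig, cochrans_q, harmonize,
                   ivw, leave_one_out, mr_egger, simulate_two_sample,
                   wald_ratios, weighted_median)
from mrkit.estimators import _weighted_median_point

from conftest import make_harmonized


class TestWaldRatios:
    def test_simple_ratios(self):
        h = make_harmonized([1.0, 1.0], [0.1, 0.1], [0.5, 0.5])
        wr = wald_ratios(h)
        np.testing.assert_allclose(wr.ratio, [0.5, 0.5])
        np.testing.assert_allclose(wr.se, [0.1, 0.1])

    def test_first_order_se(self):
        h = make_harmonized([2.0, 1.0], [0.2, 0.1], [0.8, 0.1])
        wr = wald_ratios(h)
        assert wr.ratio[0] == pytest.approx(0.4)
        assert wr.se[0] == pytest.approx(0.1)

    def test_sign_flip_invariance(self):
        h1 = make_harmonized([1.0, 2.0, -1.5], [0.1, 0.1, 0.1], [0.3, 0.7, -0.4])
        h2 = make_harmonized([1.0, 2.0, 1.5], [0.1, 0.1, 0.1], [0.3, 0.7, 0.4])
        np.testing.assert_allclose(wald_ratios(h1).ratio, wald_ratios(h2).ratio)

    def test_zero_betas_dropped_with_count(self):
        h = make_harmonized([1.0, 0.0, 2.0], [0.1] * 3, [0.3, 0.1, 0.8])
        wr = wald_ratios(h)
        assert wr.n_dropped_zero_beta == 1
        assert len(wr.ratio) == 2

    def test_all_zero_is_an_error(self):
        h = make_harmonized([0.0, 0.0], [0.1, 0.1], [0.3, 0.1])
        with pytest.raises(EstimationError):
            wald_ratios(h)


class TestIvw:
    def test_worked_example(self):
        """Hand weighted-least-squares oracle with w = (100, 25)."""
        h = make_harmonized([1.0, 2.0], [0.1, 0.2], [0.3, 0.8])
        est, het = ivw(h)
        assert est.beta == pytest.approx(0.35, abs=1e-12)
        assert est.se == pytest.approx(0.070711, abs=1e-6)  # Q/(J-1) < 1 -> fixed SE
        assert het.q_stat == pytest.approx(0.5, abs=1e-12)
        assert het.df == 1

    def test_identical_ratios_give_zero_q_and_fixed_se(self):
        h = make_harmonized([1.0, 2.0, 4.0], [0.1, 0.1, 0.1], [0.3, 0.6, 1.2])
        est_re, het = ivw(h, random_effects="multiplicative")
        est_fe, _ = ivw(h, random_effects="fixed")
        assert het.q_stat == pytest.approx(0.0, abs=1e-20)
        assert est_re.se == est_fe.se

    def test_ratio_form_equals_regression_form(self):
        """IVW is the zero-intercept WLS of outcome on exposure betas."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            j = rng.integers(2, 12)
            bx = rng.normal(0, 1, j)
            by = rng.normal(0, 1, j)
            sy = rng.uniform(0.05, 0.5, j)
            est, _ = ivw(make_harmonized(bx, sy, by), random_effects="fixed")
            sw = 1.0 / sy
            slope = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)[0][0]
            assert est.beta == pytest.approx(slope, abs=1e-10)

    def test_fewer_than_two_snps_rejected(self):
        with pytest.raises(EstimationError):
            ivw(make_harmonized([1.0], [0.1], [0.3]))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        bx, by, sy = rng.normal(1, 0.3, 8), rng.normal(0.5, 0.2, 8), rng.uniform(0.05, 0.2, 8)
        c = 3.7
        est1, _ = ivw(make_harmonized(bx, sy, by))
        est2, _ = ivw(make_harmonized(c * bx, sy, by))
        assert est2.beta == pytest.approx(est1.beta / c, rel=1e-12)


class TestEgger:
    def test_collinear_points_recover_slope_and_intercept(self):
        h = make_harmonized([1.0, 2.0, 3.0], [0.1] * 3, [0.4, 0.7, 1.0])
        est, het = mr_egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert het.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_orientation_invariance(self):
        """Flipping a SNP's allele orientation must not move the estimates."""
        h1 = make_harmonized([1.0, 2.0, 3.0, 1.5], [0.1] * 4, [0.4, 0.7, 1.0, 0.5])
        h2 = make_harmonized([1.0, -2.0, 3.0, 1.5], [0.1] * 4, [0.4, -0.7, 1.0, 0.5])
        e1, h_1 = mr_egger(h1)
        e2, h_2 = mr_egger(h2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert h_1.egger_intercept == pytest.approx(h_2.egger_intercept, rel=1e-12)

    def test_directional_pleiotropy_recovers_mean_alpha_noiseless(self):
        """In the noiseless limit the intercept IS the average direct effect."""
        study = simulate_two_sample(SimulationConfig(
            seed=1, theta=0.157, noiseless=True,
            pleiotropy_mode="directional", pleiotropy_mean=0.02, pleiotropy_sd=0.0))
        h = harmonize(study.exposure_stats, study.outcome_stats)
        est, het = mr_egger(h)
        assert het.egger_intercept == pytest.approx(0.02, abs=1e-10)
        assert est.beta == pytest.approx(0.157, abs=1e-10)

    def test_directional_pleiotropy_intercept_consistency(self):
        """With sampling noise the mean intercept tracks the mean direct
        effect; weak instruments whose observed exposure effect flips sign
        under orientation attenuate it somewhat (finite-sample behaviour of
        the estimator, not a bug)."""
        cfg_kw = dict(theta=0.157, pleiotropy_mode="directional",
                      pleiotropy_mean=0.02, pleiotropy_sd=0.0)
        intercepts = []
        for seed in range(200):
            study = simulate_two_sample(SimulationConfig(seed=seed, **cfg_kw))
            h = harmonize(study.exposure_stats, study.outcome_stats)
            _, het = mr_egger(h)
            intercepts.append(het.egger_intercept)
        mean = np.mean(intercepts)
        assert 0.7 * 0.02 < mean < 1.1 * 0.02

    def test_too_few_snps_rejected(self):
        with pytest.raises(EstimationError):
            mr_egger(make_harmonized([1.0, 2.0], [0.1] * 2, [0.3, 0.6]))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1] * 3, [0.2, 0.5, 0.9])
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_hand_interpolated_example(self):
        """Ratios (0.1, 0.4, 1.0) with weights (1, 1, 2) interpolate to 0.6."""
        ratio = np.array([0.1, 0.4, 1.0])
        weight = np.array([1.0, 1.0, 2.0])
        assert _weighted_median_point(ratio, weight) == pytest.approx(0.6, abs=1e-12)
        # same through the public API: weights b_x^2/se_y^2
        bx = np.array([1.0, 1.0, np.sqrt(2.0)])
        by = ratio * bx
        est = weighted_median(make_harmonized(bx, np.ones(3), by), n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.6, abs=1e-12)

    def test_matches_weighted_absolute_deviation_minimizer(self):
        """Independent oracle: grid search over the WAD objective.

        The interpolated weighted median and the WAD minimizer coincide up
        to the local gap between adjacent order statistics (they are equal
        in the dense limit), so the tolerance is grid step + local gap.
        """
        rng = np.random.default_rng(7)
        grid_step = 1e-3
        for _ in range(25):
            j = int(rng.integers(5, 40))
            ratio = rng.uniform(-1, 1, j)
            weight = rng.uniform(0.1, 5.0, j)
            grid = np.arange(-1.2, 1.2, grid_step)
            wad = np.abs(grid[:, None] - ratio[None, :]) @ weight
            oracle = grid[np.argmin(wad)]
            point = _weighted_median_point(ratio, weight)
            srt = np.sort(ratio)
            k = np.searchsorted(srt, oracle)
            local_gap = (srt[min(k + 1, j - 1)] - srt[max(k - 1, 0)])
            assert abs(point - oracle) <= local_gap + 2 * grid_step

    def test_bootstrap_se_is_seed_reproducible(self):
        h = make_harmonized([1.0, 1.2, 0.8, 1.1], [0.1] * 4, [0.3, 0.4, 0.2, 0.35],
                            sx=[0.05] * 4)
        a = weighted_median(h, n_boot=200, seed=5)
        b = weighted_median(h, n_boot=200, seed=5)
        c = weighted_median(h, n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se
        with pytest.raises(EstimationError):
            weighted_median(h, n_boot=200, seed=None)
        with pytest.raises(EstimationError):
            weighted_median(h, n_boot=50, seed=1)


class TestCochransQ:
    def test_identical_ratios_boundary(self):
        h = make_harmonized([1.0, 2.0], [0.1, 0.2], [0.4, 0.8])
        res = cochrans_q(h, 0.4)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    def test_worked_example_chi_square_tail(self):
        h = make_harmonized([1.0, 2.0], [0.1, 0.2], [0.3, 0.8])
        est, _ = ivw(h)
        res = cochrans_q(h, est.beta)
        assert res.q_stat == pytest.approx(0.5, abs=1e-12)
        assert res.pval == pytest.approx(stats.chi2.sf(0.5, 1), abs=1e-12)
        assert res.pval == pytest.approx(0.4795, abs=1e-4)

    def test_balanced_pleiotropy_inflates_q(self):
        qs = []
        for seed in range(80):
            study = simulate_two_sample(SimulationConfig(
                seed=seed, theta=0.1, pleiotropy_mode="balanced", pleiotropy_sd=0.003))
            h = harmonize(study.exposure_stats, study.outcome_stats)
            est, het = ivw(h)
            qs.append(het.q_stat / het.df)
        assert np.mean(qs) > 1.3


class TestLeaveOneOut:
    def test_identical_snps_all_equal_full(self):
        h = make_harmonized([1.0] * 5, [0.1] * 5, [0.3] * 5)
        res = leave_one_out(h)
        np.testing.assert_allclose(res.table["beta"], res.full.beta)
        assert len(res.table) == 5
        assert res.influential == []

    def test_planted_outlier_has_largest_shift(self):
        bx = np.ones(10)
        by = np.full(10, 0.3)
        by[4] = 1.5  # gross outlier
        res = leave_one_out(make_harmonized(bx, np.full(10, 0.1), by))
        shifts = np.abs(res.table["beta"] - res.full.beta)
        assert res.table.loc[shifts.idxmax(), "omitted_snp"] == "rs5"

    def test_output_length_is_always_j(self, small_study):
        h = harmonize(small_study.exposure_stats, small_study.outcome_stats)
        res = leave_one_out(h)
        assert len(res.table) == h.n_snps


def test_estimators_converge_to_theta_without_pleiotropy():
    """All three estimator means approach the generative effect."""
    theta = 0.157
    betas = {"ivw": [], "wm": [], "egger": []}
    for seed in range(300):
        study = simulate_two_sample(SimulationConfig(theta=theta, seed=10_000 + seed))
        h = harmonize(study.exposure_stats, study.outcome_stats)
        betas["ivw"].append(ivw(h)[0].beta)
        betas["wm"].append(weighted_median(h, n_boot=100, seed=seed).beta)
        betas["egger"].append(mr_egger(h)[0].beta)
    for method, values in betas.items():
        mean = np.mean(values)
        mc3 = 3 * np.std(values, ddof=1) / np.sqrt(len(values))
        assert mean == pytest.approx(theta, abs=mc3), method
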