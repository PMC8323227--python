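"""Estimator battery: arithmetic examples, brute-force oracles,
robustness fixtures, equivariance and determinism properties."""

import numpy as np
import pytest
from scipy.stats import chi2

from tsmr.estimators import (
    ConfigurationError,
    EstimatorError,
    MultiExposureSet,
    SuiteConfig,
    cochran_q,
    ivw_random_effects,
    mode_based_estimate,
    mr_egger,
    mr_presso,
    mr_raps,
    mr_robust,
    multivariable_ivw,
    raps_objective,
    ratio_estimates,
    run_estimator_suite,
    wald_ratio,
    weighted_median,
    _mbe_point,
    _weighted_median,
)

from conftest import make_hset, sim_hset


class TestWaldRatio:
    def test_arithmetic(self):
        hset = make_hset([0.05], [0.01], [0.025], [0.005])
        est = wald_ratio(hset.instruments[0])
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        hset = make_hset([0.05], [0.01], [0.0], [0.005])
        assert wald_ratio(hset.instruments[0]).beta == 0.0

    def test_zero_exposure_effect_errors(self):
        hset = make_hset([0.0], [0.01], [0.1], [0.005])
        with pytest.raises(EstimatorError):
            wald_ratio(hset.instruments[0])

    def test_first_order_se_matches_bootstrap_oracle(self):
        """Parametric-bootstrap oracle for the ratio SE at strong
        instrument strength: the neglected second-order term scales as
        (ratio * se_exp / gamma)^2, so at |gamma|/se_exp = 25 the
        first-order SE agrees within 5%."""
        g, sx, G, sy = 0.05, 0.002, 0.025, 0.005
        rng = np.random.default_rng(2024)
        draws = rng.normal(G, sy, 100_000) / rng.normal(g, sx, 100_000)
        first_order = sy / abs(g)
        assert abs(np.std(draws) - first_order) / first_order < 0.05


class TestIVW:
    def test_single_snp_equals_wald(self):
        hset = make_hset([0.05], [0.01], [0.025], [0.005])
        ivw = ivw_random_effects(hset)
        wald = wald_ratio(hset.instruments[0])
        assert ivw.beta == wald.beta and ivw.se == wald.se

    def test_collinear_set_has_zero_heterogeneity(self):
        g = np.array([0.05, 0.1, 0.2])
        hset = make_hset(g, g * 0 + 0.01, 0.5 * g, g * 0 + 0.02)
        est = ivw_random_effects(hset)
        assert est.beta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-20)
        assert est.q_p == pytest.approx(1.0)

    def test_matches_wls_normal_equations_oracle(self):
        """IVW equals WLS of Gamma on gamma through the origin with
        weights 1/se_out², solved by hand-rolled normal equations."""
        rng = np.random.default_rng(7)
        g = rng.uniform(0.05, 0.3, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        G = 0.4 * g + rng.normal(0, sy)
        hset = make_hset(g, g * 0 + 0.01, G, sy)
        w = 1 / sy**2
        beta_wls = np.sum(w * g * G) / np.sum(w * g * g)
        assert ivw_random_effects(hset).beta == pytest.approx(beta_wls, abs=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(EstimatorError):
            ivw_random_effects(make_hset([], [], [], []))


class TestCochranQ:
    def test_identical_ratios(self):
        hset = make_hset([0.1, 0.1], [0.01] * 2, [0.05, 0.05], [0.01] * 2)
        q, df, p = cochran_q(ratio_estimates(hset), 0.5)
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # ratios 0 and 1, both se 1, center 0.5: Q = 0.25 + 0.25
        hset = make_hset([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        q, df, _ = cochran_q(ratio_estimates(hset), 0.5)
        assert q == pytest.approx(0.5) and df == 1

    def test_single_ratio_errors(self):
        hset = make_hset([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(EstimatorError):
            cochran_q(ratio_estimates(hset), 0.0)

    def test_null_distribution_is_chi_square(self):
        """Under homogeneity Q ~ chi²(J-1): rejection at 0.05 within
        0.05 ± 0.013 over 2,000 seeded replicates."""
        rng = np.random.default_rng(31)
        J, reps = 8, 2000
        se = np.full(J, 0.1)
        crit = chi2.ppf(0.95, J - 1)
        rej = 0
        for _ in range(reps):
            b = rng.normal(0.3, se)
            w = 1 / se**2
            center = np.sum(w * b) / np.sum(w)
            rej += np.sum(w * (b - center) ** 2) > crit
        assert abs(rej / reps - 0.05) <= 0.013


class TestEgger:
    def test_exact_linear_data(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.02 + 0.4 * g
        hset = make_hset(g, g * 0 + 0.01, G, g * 0 + 0.02)
        est = mr_egger(hset)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_no_spread_errors(self):
        hset = make_hset([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3)
        with pytest.raises(EstimatorError):
            mr_egger(hset)

    def test_orientation_invariance(self):
        """Re-signing instruments to gamma >= 0 makes the fit invariant
        to which allele the exposure effect is reported for."""
        g = np.array([0.05, -0.1, 0.2, 0.3])
        G = 0.4 * g + np.array([0.01, -0.02, 0.015, 0.0])
        hset = make_hset(g, np.abs(g) * 0 + 0.01, G, np.abs(g) * 0 + 0.02)
        hset_flipped = make_hset(-g, np.abs(g) * 0 + 0.01, -G, np.abs(g) * 0 + 0.02)
        a, b = mr_egger(hset), mr_egger(hset_flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_balanced_pleiotropy_intercept_size(self):
        """Mean-zero pleiotropy: the intercept test rejects at ~5%
        (2,000 seeded replicates, 3 MC-SE band)."""
        from tsmr import PleiotropyConfig
        rej = 0
        reps = 2000
        for r in range(reps):
            hset = sim_hset(
                (5, 10, r), beta=0.3,
                pleiotropy=PleiotropyConfig(
                    mode="balanced", sd_alpha=0.01, invalid_fraction=1.0
                ),
            )
            rej += mr_egger(hset).egger_intercept_p < 0.05
        assert abs(rej / reps - 0.05) <= 0.013


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        hset = make_hset([1.0] * 3, [0.01] * 3, [0.2, 0.5, 0.9], [1.0] * 3)
        assert weighted_median(hset, 100, 0).beta == pytest.approx(0.5)

    def test_small_bootstrap_rejected(self):
        hset = make_hset([1.0] * 3, [0.01] * 3, [0.2, 0.5, 0.9], [1.0] * 3)
        with pytest.raises(ConfigurationError):
            weighted_median(hset, n_boot=99)

    def test_interpolation_matches_cdf_scan_oracle(self):
        """Brute-force scan over the empirical weighted CDF."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            b = rng.normal(0, 1, 9)
            w = rng.uniform(0.1, 3, 9)
            order = np.argsort(b)
            bs, ws = b[order], w[order]
            s = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
            # dense scan of the piecewise-linear CDF inverse
            grid = np.linspace(bs[0], bs[-1], 20001)
            cdf = np.interp(grid, bs, s)
            oracle = grid[int(np.argmin(np.abs(cdf - 0.5)))]
            assert _weighted_median(b, w) == pytest.approx(oracle, abs=1e-3)

    def test_tracks_valid_majority_with_three_invalid(self):
        """7 valid instruments at ratio 0.3, 3 with large positive
        pleiotropy: the median stays with the majority."""
        rng = np.random.default_rng(99)
        g = rng.uniform(0.05, 0.12, 10)
        sy = np.full(10, 0.004)
        alpha = np.zeros(10)
        alpha[:3] = 0.05
        G = 0.3 * g + alpha + rng.normal(0, sy)
        hset = make_hset(g, np.full(10, 0.002), G, sy)
        est = weighted_median(hset, 500, 1)
        assert abs(est.beta - 0.3) < 0.05


class TestModeBasedEstimate:
    def test_degenerate_identical_ratios(self):
        hset = make_hset([1.0] * 3, [0.01] * 3, [0.5] * 3, [1.0] * 3)
        assert mode_based_estimate(hset, 1.0, 100, 0).beta == pytest.approx(0.5)

    def test_majority_mode_wins_bimodal(self):
        rng = np.random.default_rng(17)
        ratios = np.concatenate([rng.normal(0.3, 0.01, 7), rng.normal(1.2, 0.01, 3)])
        g = np.full(10, 1.0)
        hset = make_hset(g, g * 0.01, ratios, np.full(10, 0.05))
        est = mode_based_estimate(hset, 1.0, 200, 3)
        assert abs(est.beta - 0.3) < 0.05

    def test_grid_matches_dense_refinement_oracle(self):
        """Brute-force density evaluation at 10x grid resolution agrees
        within one coarse grid step."""
        rng = np.random.default_rng(8)
        b = rng.normal(0.4, 0.1, 12)
        w = rng.uniform(0.5, 2.0, 12)
        point, step = _mbe_point(b, w, 1.0, n_grid=512)
        dense, _ = _mbe_point(b, w, 1.0, n_grid=5120)
        assert abs(point - dense) <= step

    def test_bad_phi_rejected(self):
        hset = make_hset([1.0] * 3, [0.01] * 3, [0.5] * 3, [1.0] * 3)
        with pytest.raises(ConfigurationError):
            mode_based_estimate(hset, phi=0.0)


class TestPresso:
    def test_too_few_simulations_rejected(self, clean_hset):
        with pytest.raises(ConfigurationError):
            mr_presso(clean_hset, n_sim=999)

    def test_too_few_instruments_rejected(self):
        hset = make_hset([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3)
        with pytest.raises(EstimatorError):
            mr_presso(hset, 1000)

    def test_planted_outlier_flagged_and_corrected(self):
        """One instrument with a 10x ratio among 12: it is flagged (an
        outlier this extreme also contaminates the leave-one-out slopes
        of its neighbours, so further flags are possible) and the
        corrected estimate recovers the truth."""
        hset = sim_hset((21, 0), beta=0.3, n_snps=12)
        bad = hset.instruments[3]
        object.__setattr__(bad, "beta_out", 3.0 * bad.beta_exp)
        est = mr_presso(hset, n_sim=2000, seed=4)
        assert bad.snp_id in est.outliers
        assert est.presso_global_p < 0.01
        assert abs(est.beta - 0.3) < 0.05
        assert est.distortion_p is not None

    def test_seed_reproducibility(self, clean_hset):
        a = mr_presso(clean_hset, 1000, seed=9)
        b = mr_presso(clean_hset, 1000, seed=9)
        assert a.presso_global_p == b.presso_global_p and a.beta == b.beta


class TestRobust:
    def test_clean_exact_data_matches_ivw(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        hset = make_hset(g, g * 0 + 0.01, 0.4 * g, g * 0 + 0.02)
        assert abs(mr_robust(hset).beta - ivw_random_effects(hset).beta) < 1e-6

    def test_downweights_gross_outlier(self):
        rng = np.random.default_rng(12)
        g = rng.uniform(0.05, 0.3, 20)
        sy = np.full(20, 0.004)
        G = 0.3 * g + rng.normal(0, sy)
        G[7] += 0.5  # gross outlier
        hset = make_hset(g, np.full(20, 0.002), G, sy)
        clean = make_hset(np.delete(g, 7), np.full(19, 0.002),
                          np.delete(G, 7), np.delete(sy, 7))
        target = ivw_random_effects(clean).beta
        robust = mr_robust(hset).beta
        plain = ivw_random_effects(hset).beta
        assert abs(robust - target) < 0.02
        assert abs(plain - target) > abs(robust - target)

    def test_converged_point_is_fixed_point(self, clean_hset):
        est = mr_robust(clean_hset)
        again = mr_robust(clean_hset, start=est.beta)
        assert again.beta == pytest.approx(est.beta, abs=1e-9)


class TestRaps:
    def test_noiseless_proportional_data_exact(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        hset = make_hset(g, g * 0 + 1e-8, 0.4 * g, g * 0 + 0.02)
        est = mr_raps(hset)
        assert est.beta == pytest.approx(0.4, abs=1e-6)
        assert est.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_ivw_without_pleiotropy(self):
        hset = sim_hset((33, 0), beta=0.3, n_snps=50)
        ivw = ivw_random_effects(hset)
        raps = mr_raps(hset)
        assert abs(raps.beta - ivw.beta) < 0.5 * ivw.se

    def test_optimum_matches_2d_grid_oracle(self, clean_hset):
        g, sx, G, sy = clean_hset.arrays()
        est = mr_raps(clean_hset)
        betas = np.linspace(est.beta - 0.05, est.beta + 0.05, 101)
        tau2s = np.linspace(0, max(est.tau2 * 2, 1e-4), 101)
        vals = np.array(
            [[raps_objective(b, t, g, sx, G, sy) for t in tau2s] for b in betas]
        )
        bi, ti = np.unravel_index(np.argmin(vals), vals.shape)
        assert abs(betas[bi] - est.beta) <= betas[1] - betas[0]
        assert abs(tau2s[ti] - est.tau2) <= tau2s[1] - tau2s[0]


class TestMultivariableIVW:
    def test_exact_two_exposure_recovery(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.05, 0.3, (8, 2))
        y = 0.3 * X[:, 0] + 0.0 * X[:, 1]
        mset = MultiExposureSet(
            [f"rs{i}" for i in range(8)], ["e1", "e2"],
            X, np.full((8, 2), 0.01), y, np.full(8, 0.02),
        )
        ests = multivariable_ivw(mset)
        assert ests[0].beta == pytest.approx(0.3, abs=1e-10)
        assert ests[1].beta == pytest.approx(0.0, abs=1e-10)

    def test_single_exposure_reduces_to_ivw(self, clean_hset):
        g, sx, G, sy = clean_hset.arrays()
        mset = MultiExposureSet(
            clean_hset.snp_ids, ["e"], g[:, None], sx[:, None], G, sy
        )
        mv = multivariable_ivw(mset)[0]
        ivw = ivw_random_effects(clean_hset)
        assert mv.beta == pytest.approx(ivw.beta, abs=1e-12)
        assert mv.se == pytest.approx(ivw.se, rel=1e-10)

    def test_matches_wls_normal_equations_oracle(self):
        rng = np.random.default_rng(44)
        X = rng.uniform(-0.3, 0.3, (20, 2))
        sy = rng.uniform(0.01, 0.05, 20)
        y = 0.2 * X[:, 0] - 0.1 * X[:, 1] + rng.normal(0, sy)
        mset = MultiExposureSet(
            [f"rs{i}" for i in range(20)], ["e1", "e2"],
            X, np.full((20, 2), 0.01), y, sy,
        )
        W = np.diag(1 / sy**2)
        oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        ests = multivariable_ivw(mset)
        assert ests[0].beta == pytest.approx(oracle[0], abs=1e-12)
        assert ests[1].beta == pytest.approx(oracle[1], abs=1e-12)

    def test_collinear_design_rejected(self):
        X = np.ones((5, 2)) * np.array([[1.0, 2.0]])
        X[:, 0] = np.arange(1, 6)
        X[:, 1] = 2 * X[:, 0]
        mset = MultiExposureSet(
            [f"rs{i}" for i in range(5)], ["e1", "e2"],
            X, np.full((5, 2), 0.01), np.ones(5), np.full(5, 0.02),
        )
        with pytest.raises(EstimatorError, match="collinear"):
            multivariable_ivw(mset)


class TestSuite:
    def test_single_snp_runs_ivw_only(self):
        hset = make_hset([0.05], [0.01], [0.025], [0.005])
        suite = run_estimator_suite(hset)
        assert [e.method for e in suite.estimates] == ["ivw_re"]
        assert set(suite.failures) == {
            "egger", "weighted_median", "presso", "mbe", "robust", "raps"
        }

    def test_clean_simulation_recovers_truth(self, clean_hset):
        suite = run_estimator_suite(
            clean_hset, SuiteConfig(seed=2, presso_n_sim=1000)
        )
        assert len(suite.estimates) == 7
        for est in suite.estimates:
            assert abs(est.beta - 0.3) < 2 * est.se, est.method

    def test_output_schema_and_determinism(self, clean_hset):
        cfg = SuiteConfig(seed=5, presso_n_sim=1000)
        f1 = run_estimator_suite(clean_hset, cfg).to_frame()
        f2 = run_estimator_suite(clean_hset, cfg).to_frame()
        assert list(f1["method"]) == list(SuiteConfig().methods)
        assert f1.equals(f2)


class TestEquivariance:
    @pytest.mark.parametrize("c", [2.5, -1.0])
    def test_outcome_scale_and_sign_equivariance(self, clean_hset, c):
        """Scaling all outcome effects and SEs by |c| (and flipping the
        sign for c < 0) scales/flips every method's estimate."""
        g, sx, G, sy = clean_hset.arrays()
        scaled = make_hset(g, sx, c * G, abs(c) * sy)
        deterministic = [
            lambda h: ivw_random_effects(h),
            lambda h: mr_egger(h),
            lambda h: mr_robust(h),
            lambda h: mr_raps(h),
        ]
        for fn in deterministic:
            base, tr = fn(clean_hset), fn(scaled)
            assert tr.beta == pytest.approx(c * base.beta, rel=1e-4, abs=1e-8)
            assert tr.se == pytest.approx(abs(c) * base.se, rel=1e-3)
        stochastic = [
            lambda h: weighted_median(h, 200, 7),
            lambda h: mode_based_estimate(h, 1.0, 200, 7),
        ]
        for fn in stochastic:
            base, tr = fn(clean_hset), fn(scaled)
            assert tr.beta == pytest.approx(c * base.beta, rel=1e-6, abs=1e-10)
            # bootstrap SEs share the scale but not the exact draws
            assert tr.se == pytest.approx(abs(c) * base.se, rel=0.3)
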