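import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radialmvmr import (SummaryDataset, adjust_points, conditional_F,
                        detect_outliers, exposure_Q, fit_radial_ivw,
                        fit_radial_mvmr, mvmr_weights, prune_iterative)

from conftest import random_dataset


def normal_equations_wls(ds):
    """Independent oracle: (XᵀWX)⁻¹XᵀWy on the raw associations with W=1/σ̂²_Y."""
    W = np.diag(1.0 / ds.se_Gamma ** 2)
    X = ds.gamma
    return np.linalg.inv(X.T @ W @ X) @ (X.T @ W @ ds.Gamma)


class TestWeights:
    def test_direct_value(self):
        ds = SummaryDataset(["a", "b"], ["X1"], [[3.0], [1.0]], [[0.1], [0.1]],
                            [1.0, 1.0], [1.0, 2.0])
        np.testing.assert_allclose(mvmr_weights(ds)[:, 0], [9.0, 0.25])

    def test_k1_reduces_to_univariable_weight(self, rng):
        ds = random_dataset(rng, n_snps=15, n_exposures=1)
        np.testing.assert_allclose(mvmr_weights(ds)[:, 0],
                                   ds.gamma[:, 0] ** 2 / ds.se_Gamma ** 2)

    def test_sqrt_weight_algebra(self, rng):
        ds = random_dataset(rng, n_snps=25, n_exposures=3)
        np.testing.assert_allclose(np.sqrt(mvmr_weights(ds)),
                                   np.abs(ds.gamma) / ds.se_Gamma[:, None])


class TestFit:
    def test_k1_reduction_to_univariable(self, rng):
        ds = random_dataset(rng, n_snps=30, n_exposures=1)
        uni = fit_radial_ivw(ds, "X1")
        mv = fit_radial_mvmr(ds)
        assert mv.beta[0] == pytest.approx(uni.beta_ivw, rel=1e-10)
        assert mv.Q_exposure[0] == pytest.approx(uni.Q_global, rel=1e-10)
        np.testing.assert_allclose(np.sort(mv.per_snp_Q[:, 0]),
                                   np.sort(uni.per_snp["Q"]), rtol=1e-10)
        assert mv.se[0] == pytest.approx(uni.se, rel=1e-10)

    def test_noiseless_recovery(self, rng):
        beta_true = np.array([1.0, 0.2, -0.5])
        gamma = rng.normal(0, 5, (40, 3))
        ds = SummaryDataset([f"rs{j}" for j in range(40)], ["X1", "X2", "X3"],
                            gamma, np.full((40, 3), 0.1), gamma @ beta_true,
                            np.full(40, 0.3))
        fit = fit_radial_mvmr(ds)
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-8)
        np.testing.assert_allclose(fit.Q_exposure, 0, atol=1e-12)

    def test_matches_normal_equations_wls(self, rng):
        for _ in range(50):
            ds = random_dataset(rng, n_snps=25, n_exposures=3)
            np.testing.assert_allclose(fit_radial_mvmr(ds).beta,
                                       normal_equations_wls(ds), rtol=1e-8)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm
        ds = random_dataset(rng, n_snps=40, n_exposures=3)
        res = sm.WLS(ds.Gamma, ds.gamma, weights=1.0 / ds.se_Gamma ** 2).fit()
        fit = fit_radial_mvmr(ds)
        np.testing.assert_allclose(fit.beta, res.params, rtol=1e-8)

    def test_too_few_snps_errors(self, rng):
        ds = random_dataset(rng, n_snps=3, n_exposures=3)
        with pytest.raises(ValueError, match="J=3"):
            fit_radial_mvmr(ds)

    def test_collinear_exposures_named(self, rng):
        ds = random_dataset(rng, n_snps=20, n_exposures=2)
        dup = SummaryDataset(ds.snp_ids, ["A", "B", "C"],
                             np.column_stack([ds.gamma, 2 * ds.gamma[:, 0]]),
                             np.column_stack([ds.se_gamma, ds.se_gamma[:, 0]]),
                             ds.Gamma, ds.se_Gamma)
        with pytest.raises(ValueError, match="collinear.*A.*C"):
            fit_radial_mvmr(dup)

    def test_all_zero_snps_dropped_before_fit(self, rng):
        ds = random_dataset(rng, n_snps=20, n_exposures=2)
        gam = ds.gamma.copy()
        gam[5] = 0.0
        ds0 = SummaryDataset(ds.snp_ids, ds.exposure_names, gam, ds.se_gamma,
                             ds.Gamma, ds.se_Gamma)
        fit = fit_radial_mvmr(ds0)
        assert fit.n_snps_used == 19 and "rs6" not in fit.snp_ids


class TestAdjustmentAndQ:
    def test_k1_adjustment_is_identity(self, rng):
        ds = random_dataset(rng, n_snps=12, n_exposures=1)
        fit = fit_radial_mvmr(ds)
        for p in adjust_points(ds, fit):
            assert p.y_adjusted == pytest.approx(p.y_unadjusted)

    def test_exposure_specific_instrument_unadjusted(self, rng):
        # a SNP associated with only the reference exposure gets no adjustment
        ds = random_dataset(rng, n_snps=12, n_exposures=2)
        gam = ds.gamma.copy()
        gam[0, 1] = 0.0
        ds = SummaryDataset(ds.snp_ids, ds.exposure_names, gam, ds.se_gamma,
                            ds.Gamma, ds.se_Gamma)
        fit = fit_radial_mvmr(ds)
        p0 = [p for p in adjust_points(ds, fit)
              if p.snp_id == "rs1" and p.exposure == "X1"][0]
        assert p0.y_adjusted == pytest.approx(p0.y_unadjusted)

    def test_ratio_recovered_from_point(self, rng):
        ds = random_dataset(rng, n_snps=10, n_exposures=3)
        fit = fit_radial_mvmr(ds)
        k = {n: i for i, n in enumerate(ds.exposure_names)}
        j = {s: i for i, s in enumerate(ds.snp_ids)}
        for p in adjust_points(ds, fit):
            g = ds.gamma[j[p.snp_id], k[p.exposure]]
            if g != 0:
                assert p.y_unadjusted / p.x == pytest.approx(
                    ds.Gamma[j[p.snp_id]] / g, rel=1e-9)
            assert p.x >= 0

    def test_residual_identity(self, rng):
        """Squared distance of each adjusted point to its line equals Q_kj."""
        ds = random_dataset(rng, n_snps=18, n_exposures=3)
        fit = fit_radial_mvmr(ds)
        k = {n: i for i, n in enumerate(ds.exposure_names)}
        j = {s: i for i, s in enumerate(ds.snp_ids)}
        for p in adjust_points(ds, fit):
            expected = fit.per_snp_Q[j[p.snp_id], k[p.exposure]]
            resid2 = (p.y_adjusted - fit.beta[k[p.exposure]] * p.x) ** 2
            assert resid2 == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_Q_decomposition(self, rng):
        ds = random_dataset(rng, n_snps=22, n_exposures=3)
        fit = fit_radial_mvmr(ds)
        np.testing.assert_allclose(fit.per_snp_Q.sum(axis=0), fit.Q_exposure,
                                   rtol=1e-10)
        Qk, Qkj, pkj = exposure_Q(ds, fit)
        np.testing.assert_allclose(Qk, fit.Q_exposure, rtol=1e-12)
        np.testing.assert_allclose(Qkj, fit.per_snp_Q, rtol=1e-12)

    def test_direct_effect_snp_dominates_Q(self, rng):
        # noiseless data except one SNP given a direct outcome effect
        beta_true = np.array([0.5, -0.3])
        gamma = rng.normal(0, 5, (20, 2))
        Gamma = gamma @ beta_true
        Gamma[7] += 4.0
        ds = SummaryDataset([f"rs{j}" for j in range(20)], ["X1", "X2"],
                            gamma, np.full((20, 2), 0.1), Gamma, np.full(20, 0.3))
        fit = fit_radial_mvmr(ds)
        for k in range(2):
            assert fit.per_snp_Q[:, k].argmax() == 7

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), flip=st.integers(0, 17))
    def test_sign_flip_invariance(self, seed, flip):
        """Jointly flipping a SNP's association signs leaves the fit unchanged."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_snps=18, n_exposures=3)
        gam, Gam = ds.gamma.copy(), ds.Gamma.copy()
        gam[flip] *= -1
        Gam[flip] *= -1
        flipped = SummaryDataset(ds.snp_ids, ds.exposure_names, gam,
                                 ds.se_gamma, Gam, ds.se_Gamma)
        f0, f1 = fit_radial_mvmr(ds), fit_radial_mvmr(flipped)
        np.testing.assert_allclose(f0.beta, f1.beta, rtol=1e-9)
        np.testing.assert_allclose(f0.per_snp_Q, f1.per_snp_Q, rtol=1e-8)


class TestOutlierDetection:
    def test_no_heterogeneity_empty(self, rng):
        beta_true = np.array([1.0, -1.0])
        gamma = rng.normal(0, 5, (10, 2))
        ds = SummaryDataset([f"rs{j}" for j in range(10)], ["X1", "X2"],
                            gamma, np.full((10, 2), 0.1), gamma @ beta_true,
                            np.full(10, 0.3))
        assert detect_outliers(fit_radial_mvmr(ds)) == []

    def test_union_rule_and_ordering(self, rng):
        ds = random_dataset(rng, n_snps=40, n_exposures=2)
        fit = fit_radial_mvmr(ds)
        flagged = detect_outliers(fit, alpha=0.5)
        min_p = fit.per_snp_Q_p.min(axis=1)
        expected = [fit.snp_ids[i] for i in np.argsort(min_p) if min_p[i] < 0.5]
        assert flagged == expected

    def test_bonferroni_is_stricter(self, rng):
        ds = random_dataset(rng, n_snps=40, n_exposures=2)
        fit = fit_radial_mvmr(ds)
        assert set(detect_outliers(fit, 0.05, bonferroni=True)) <= set(
            detect_outliers(fit, 0.05))

    def test_invalid_alpha(self, small_dataset):
        fit = fit_radial_mvmr(small_dataset)
        with pytest.raises(ValueError, match="alpha"):
            detect_outliers(fit, 0.0)


class TestPruning:
    def test_clean_data_converges_immediately(self, rng):
        beta_true = np.array([1.0, 0.2, -0.5])
        gamma = rng.normal(0, 5, (30, 3))
        ds = SummaryDataset([f"rs{j}" for j in range(30)], ["X1", "X2", "X3"],
                            gamma, np.full((30, 3), 0.1), gamma @ beta_true,
                            np.full(30, 0.3))
        trace = prune_iterative(ds)
        assert trace.converged and trace.iterations == []
        np.testing.assert_allclose(trace.final_fit.beta,
                                   fit_radial_mvmr(ds).beta, rtol=1e-12)

    def test_max_iter_zero_contract(self, small_dataset):
        trace = prune_iterative(small_dataset, max_iter=0)
        assert not trace.converged and trace.iterations == []
        assert trace.final_fit.n_snps_used == small_dataset.n_snps

    def test_removed_sets_disjoint_and_shrinking(self, sim_medium):
        trace = prune_iterative(sim_medium.dataset, max_iter=10)
        seen = set()
        j_prev = sim_medium.dataset.n_snps
        for removed, fit in trace.iterations:
            assert not (set(removed) & seen)
            seen |= set(removed)
            assert fit.n_snps_used == j_prev - len(removed)
            j_prev = fit.n_snps_used

    def test_converged_final_fit_has_no_outliers(self, sim_medium):
        trace = prune_iterative(sim_medium.dataset)
        assert trace.converged
        assert (trace.final_fit.per_snp_Q_p >= trace.alpha).all()

    def test_never_drops_below_floor(self, rng):
        # extreme heterogeneity so everything looks outlying
        J, K = 6, 2
        gamma = rng.normal(0, 5, (J, K))
        Gamma = rng.normal(0, 50, J)
        ds = SummaryDataset([f"rs{j}" for j in range(J)], ["X1", "X2"],
                            gamma, np.full((J, K), 0.1), Gamma, np.full(J, 0.01))
        trace = prune_iterative(ds, max_iter=20)
        assert trace.final_fit.n_snps_used >= K + 1

    def test_initial_too_small_errors(self, rng):
        ds = random_dataset(rng, n_snps=4, n_exposures=3)
        with pytest.raises(ValueError, match="K\\+2"):
            prune_iterative(ds)


class TestConditionalF:
    def test_k1_closed_form(self):
        # all γ̂/σ̂ = 10 → mean univariable F = 100
        ds = SummaryDataset([f"rs{j}" for j in range(5)], ["X1"],
                            np.full((5, 1), 2.0), np.full((5, 1), 0.2),
                            np.zeros(5), np.ones(5))
        assert conditional_F(ds)[0] == pytest.approx(100.0)

    def test_disjoint_instruments_approx_unconditional(self, rng):
        # two exposures instrumented by disjoint strong SNP sets: conditioning
        # on the other exposure should barely change instrument strength
        J = 200
        gamma = np.zeros((J, 2))
        gamma[:100, 0] = rng.normal(0, 5, 100)
        gamma[100:, 1] = rng.normal(0, 5, 100)
        gamma += rng.normal(0, 0.01, (J, 2))  # measurement-level jitter
        ds = SummaryDataset([f"rs{j}" for j in range(J)], ["X1", "X2"],
                            gamma, np.full((J, 2), 0.2), np.zeros(J), np.ones(J))
        condF = conditional_F(ds)
        uncond = (gamma ** 2 / 0.2 ** 2).mean(axis=0)
        np.testing.assert_allclose(condF, uncond, rtol=0.05)

    def test_matches_fit_attribute(self, small_dataset):
        fit = fit_radial_mvmr(small_dataset)
        np.testing.assert_allclose(fit.conditional_F, conditional_F(small_dataset))
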