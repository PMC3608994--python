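"""Maximum-likelihood fitting: closed forms, optimizer, constraints, covariates."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from platsem import (
    ConstraintMode,
    IdentificationError,
    ModelSpec,
    MomentSummary,
    NotPositiveDefiniteError,
    ParameterEstimates,
    closed_form_three_indicator,
    fit_model,
    implied_covariance,
    ml_fit_function,
    moments_from_data,
    standardize,
)
from platsem.synthetic_data import SyntheticTruth, generate, ibd_phenotype_design

from conftest import random_one_factor_moments


class TestImpliedCovariance:
    def test_perfect_indicators_give_all_ones(self):
        est = ParameterEstimates(loadings=[1, 1, 1], latent_variance=1.0,
                                 error_variances=[0, 0, 0])
        np.testing.assert_allclose(implied_covariance(est), np.ones((3, 3)))

    def test_closed_form_reproduces_the_published_triple(self, table1):
        # just-identified: plugging the estimates back reproduces the moments
        sub = table1.submatrix(["Sanger", "454_V3V5", "qPCR"])
        est, heywood = closed_form_three_indicator(sub)
        assert not heywood
        np.testing.assert_allclose(implied_covariance(est), sub.S, atol=1e-10)

    def test_zero_gamma_zeroes_the_cross_block(self):
        est = ParameterEstimates(loadings=[1, 0.9, 1.1], latent_variance=1.0,
                                 error_variances=[0.2, 0.2, 0.2],
                                 covariate_coefficients=[0.0],
                                 covariate_cov=[[0.25]])
        sigma = implied_covariance(est)
        np.testing.assert_allclose(sigma[:3, 3], 0.0)
        assert sigma[3, 3] == pytest.approx(0.25)

    def test_symmetry_with_covariates(self, rng):
        est = ParameterEstimates(loadings=[1, 0.7, 1.3], latent_variance=0.8,
                                 error_variances=[0.3, 0.4, 0.5],
                                 covariate_coefficients=[-0.5, 0.2],
                                 covariate_cov=[[0.3, 0.1], [0.1, 0.4]])
        sigma = implied_covariance(est)
        np.testing.assert_allclose(sigma, sigma.T)


class TestMlFitFunction:
    def test_zero_at_perfect_fit(self, rng):
        S = random_one_factor_moments(rng, m=4)
        assert ml_fit_function(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_for_inflated_diagonal(self):
        assert ml_fit_function(np.diag([2.0, 2.0]), np.eye(2)) == pytest.approx(
            2 * math.log(2) + 1 - 2, abs=1e-12)

    def test_equals_likelihood_ratio_oracle(self, rng):
        # F_ML = 2/(N-1) * (loglik_saturated - loglik_model), Wishart kernel
        for _ in range(10):
            S = random_one_factor_moments(rng, m=3)
            sigma = random_one_factor_moments(rng, m=3)
            n_eff = 99

            def kernel(C):
                sign, logdet = np.linalg.slogdet(C)
                return -0.5 * n_eff * (logdet + np.trace(np.linalg.solve(C, S)))

            oracle = 2.0 / n_eff * (kernel(S) - kernel(sigma))
            assert ml_fit_function(sigma, S) == pytest.approx(oracle, abs=1e-10)

    def test_non_pd_matrix_is_named(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError, match="model-implied"):
            ml_fit_function(bad, np.eye(2))


class TestClosedForm:
    def test_published_latent_variance_and_reliability(self, table1):
        sub = table1.submatrix(["Sanger", "454_V3V5", "qPCR"])
        est, _ = closed_form_three_indicator(sub)
        assert est.latent_variance == pytest.approx(0.9114, abs=5e-4)
        # reference indicator reliability on the correlation scale
        assert round(est.latent_variance / sub.S[0, 0], 3) == 0.911

    def test_exact_recovery_from_implied_moments(self, rng):
        truth = ParameterEstimates(loadings=[1, 0.8, 1.4], latent_variance=1.3,
                                   error_variances=[0.4, 0.2, 0.6])
        est, heywood = closed_form_three_indicator(implied_covariance(truth))
        assert not heywood
        np.testing.assert_allclose(est.loadings, truth.loadings, atol=1e-12)
        assert est.latent_variance == pytest.approx(1.3, abs=1e-12)
        np.testing.assert_allclose(est.error_variances, truth.error_variances,
                                   atol=1e-12)

    def test_zero_off_diagonal_unidentified(self):
        S = np.array([[1, 0.0, 0.5], [0.0, 1, 0.5], [0.5, 0.5, 1.0]])
        with pytest.raises(IdentificationError):
            closed_form_three_indicator(S)

    def test_inconsistent_signs_advise_reflection(self):
        S = np.array([[1, -0.5, 0.5], [-0.5, 1, 0.5], [0.5, 0.5, 1.0]])
        with pytest.raises(IdentificationError, match="reflect"):
            closed_form_three_indicator(S)

    def test_heywood_flagged_not_truncated(self):
        # r12*r13/r23 > 1 forces a negative error variance on indicator 1
        S = np.array([[1, 0.9, 0.9], [0.9, 1, 0.5], [0.9, 0.5, 1.0]])
        est, heywood = closed_form_three_indicator(S)
        assert heywood
        assert est.error_variances[0] < 0


class TestFitModel:
    def test_just_identified_matches_closed_form(self, table1):
        sub = table1.submatrix(["Sanger", "454_V3V5", "qPCR"])
        fit = fit_model(sub, ModelSpec(indicator_names=list(sub.names)))
        cf, _ = closed_form_three_indicator(sub)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-10)
        assert fit.df == 0
        np.testing.assert_allclose(fit.estimates.loadings, cf.loadings, atol=1e-9)

    def test_optimizer_agrees_with_closed_form(self, rng):
        for _ in range(5):
            S = random_one_factor_moments(rng, m=3)
            ms = MomentSummary(S, 200, ["a", "b", "c"])
            spec = ModelSpec(indicator_names=["a", "b", "c"])
            it = fit_model(ms, spec, use_closed_form=False, compute_se=False)
            cf = fit_model(ms, spec, compute_se=False)
            assert it.f_ml == pytest.approx(cf.f_ml, abs=1e-6)
            np.testing.assert_allclose(it.estimates.loadings,
                                       cf.estimates.loadings, atol=1e-4)

    def test_nesting_monotonicity_of_discrepancy(self, rng):
        for _ in range(4):
            S = random_one_factor_moments(rng, m=4, n_strength=3.0)
            ms = MomentSummary(S, 150, list("abcd"))
            fs = [fit_model(ms, ModelSpec(indicator_names=list("abcd"),
                                          constraint_mode=mode),
                            compute_se=False).f_ml
                  for mode in ConstraintMode]
            assert fs[0] <= fs[1] + 1e-9 <= fs[2] + 2e-9

    def test_free_mode_scale_invariance(self, table1):
        base = fit_model(table1, ModelSpec(indicator_names=list(table1.names)),
                         compute_se=False)
        D = np.diag([1.0, 7.0, 0.3, 2.5])
        scaled = MomentSummary(D @ table1.S @ D, table1.N, list(table1.names))
        alt = fit_model(scaled, ModelSpec(indicator_names=list(table1.names)),
                        compute_se=False)
        assert alt.chi_square == pytest.approx(base.chi_square, abs=1e-6)
        assert alt.df == base.df
        np.testing.assert_allclose(alt.estimates.standardized_loadings,
                                   base.estimates.standardized_loadings,
                                   atol=1e-6)

    def test_compound_symmetric_input_fits_univariate_model_exactly(self):
        m, sz, se = 4, 0.7, 0.4
        S = np.full((m, m), sz) + np.diag(np.full(m, se))
        ms = MomentSummary(S, 100, list("abcd"))
        fit = fit_model(ms, ModelSpec(
            indicator_names=list("abcd"),
            constraint_mode=ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS),
            compute_se=False)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-8)
        assert fit.estimates.latent_variance == pytest.approx(sz, abs=1e-5)
        assert fit.estimates.error_variances[0] == pytest.approx(se, abs=1e-5)

    def test_multistart_oracle_on_four_indicator_problem(self, rng):
        S = random_one_factor_moments(rng, m=4, n_strength=2.0)
        ms = MomentSummary(S, 120, list("abcd"))
        fit = fit_model(ms, ModelSpec(indicator_names=list("abcd")),
                        compute_se=False)

        def objective(x):
            lam = np.concatenate([[1.0], x[:3]])
            sigma = np.exp(x[3]) * np.outer(lam, lam) + np.diag(np.exp(x[4:8]))
            try:
                return ml_fit_function(sigma, S)
            except NotPositiveDefiniteError:
                return 1e6

        best = np.inf
        for _ in range(30):
            x0 = np.concatenate([rng.uniform(0.3, 2.0, 3),
                                 rng.uniform(-1.5, 0.5, 5)])
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "fatol": 1e-12,
                                    "xatol": 1e-10})
            best = min(best, res.fun)
        assert fit.f_ml == pytest.approx(best, abs=1e-4)

    def test_correlation_and_covariance_input_give_same_chi_square(self, rng):
        S = random_one_factor_moments(rng, m=4, n_strength=2.0)
        ms = MomentSummary(S, 120, list("abcd"))
        base = fit_model(ms, ModelSpec(indicator_names=list("abcd")),
                         compute_se=False)
        alt = fit_model(ms.to_correlation(), ModelSpec(indicator_names=list("abcd")),
                        compute_se=False)
        assert alt.chi_square == pytest.approx(base.chi_square, abs=1e-6)

    def test_non_pd_moments_rejected(self):
        S = np.array([[1, 0.99, 0.0], [0.99, 1, 0.99], [0.0, 0.99, 1.0]])
        ms = MomentSummary(S, 50, list("abc"))
        with pytest.raises(NotPositiveDefiniteError):
            fit_model(ms, ModelSpec(indicator_names=list("abc")))

    def test_parameter_recovery_with_covariates(self):
        X, names = ibd_phenotype_design(1100, 1400, 1500)
        truth = SyntheticTruth(loadings=[1.0, 0.9, 0.7],
                               latent_variance=0.9,
                               error_variances=[0.1, 0.15, 0.5],
                               gamma=[-0.6, -0.16],
                               covariate_design=X, covariate_names=names,
                               n=4000)
        data = generate(truth, seed=5)
        spec = ModelSpec(indicator_names=list(truth.platform_names),
                         covariate_names=names)
        fit = fit_model(moments_from_data(data), spec)
        est = fit.estimates
        np.testing.assert_allclose(est.covariate_coefficients, truth.gamma,
                                   atol=0.08)
        np.testing.assert_allclose(est.loadings, truth.loadings, atol=0.05)
        assert fit.standard_errors is not None
        # the large CD effect is detected, Wald p tiny
        assert fit.standard_errors["covariate_p_values"][0] < 1e-6

    def test_chi_square_n_convention(self, table1):
        spec = ModelSpec(indicator_names=list(table1.names))
        a = fit_model(table1, spec, compute_se=False)
        b = fit_model(table1, spec, n_convention="n", compute_se=False)
        assert b.chi_square / a.chi_square == pytest.approx(142 / 141)


class TestStandardize:
    def test_error_free_reference_loads_at_one(self):
        est = ParameterEstimates(loadings=[1, 0.5], latent_variance=2.0,
                                 error_variances=[0.0, 1.0])
        std = standardize(est, implied_covariance(est))
        assert std[0] == pytest.approx(1.0)

    def test_published_v3v5_standardized_loading(self, four_modality_fit):
        std = four_modality_fit.estimates.standardized_loadings
        i = four_modality_fit.spec.indicator_names.index("454_V3V5")
        assert std[i] == pytest.approx(0.955, abs=0.003)

    def test_square_equals_reliability(self, rng):
        from platsem import reliability
        for _ in range(5):
            S = random_one_factor_moments(rng, m=4, n_strength=2.0)
            ms = MomentSummary(S, 150, list("abcd"))
            fit = fit_model(ms, ModelSpec(indicator_names=list("abcd")),
                            compute_se=False)
            rep = reliability(fit)
            np.testing.assert_allclose(
                fit.estimates.standardized_loadings ** 2, rep.reliability,
                atol=1e-8)
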