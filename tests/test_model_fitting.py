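import numpy as np
import pytest
from scipy import stats

import statsmodels.api as sm

from glmsim.distributions import preset, sample_matrix
from glmsim.model_fitting import (
    DesignMatrix,
    batch_added_predictor_ftest,
    batch_binomial_slope_test,
    batch_gaussian_slope_test,
    batch_paired_lmm_slope_lrt,
    batch_poisson_slope_test,
    fit_glm,
    fit_linear,
    fit_random_intercept,
    nested_significance,
)


def _simple_fit(y, x):
    return fit_linear(y, DesignMatrix({"x": x}))


def _null_fit(y):
    return fit_linear(y, DesignMatrix({}))


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(5.0)
        fit = _simple_fit(2.0 * x, x)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(fit.residuals_response, 0.0, atol=1e-12)

    def test_hand_computed_toy(self):
        fit = _simple_fit(np.array([1.0, 2.0, 2.0, 4.0]), np.arange(4.0))
        assert fit.coefficients["x"] == pytest.approx(0.9)
        assert fit.coefficients["intercept"] == pytest.approx(0.9)

    def test_matches_pseudoinverse_solution(self, rng):
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        y = 1.0 + 0.5 * x1 - 2.0 * x2 + rng.standard_normal(40)
        fit = fit_linear(y, DesignMatrix({"x1": x1, "x2": x2}))
        X = np.column_stack([np.ones(40), x1, x2])
        beta = np.linalg.pinv(X) @ y
        assert list(fit.coefficients.values()) == pytest.approx(beta.tolist(),
                                                                abs=1e-10)
        assert abs(fit.residuals_response.sum()) < 1e-8

    def test_rank_deficiency_names_column(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_linear(x, DesignMatrix({"x": x, "dup": 2 * x}))


class TestFitGlm:
    def test_gaussian_glm_equals_ols(self, rng):
        x = rng.standard_normal(60)
        y = 0.3 * x + rng.standard_normal(60)
        a = fit_glm(y, DesignMatrix({"x": x}), "gaussian")
        b = _simple_fit(y, x)
        for name in a.coefficients:
            assert a.coefficients[name] == pytest.approx(
                b.coefficients[name], abs=1e-8
            )

    def test_poisson_null_intercept_closed_form(self, rng):
        y = rng.poisson(4.0, 200).astype(float)
        fit = fit_glm(y, DesignMatrix({}), "poisson")
        assert fit.coefficients["intercept"] == pytest.approx(np.log(y.mean()),
                                                              abs=1e-8)

    def test_quasipoisson_dispersion_near_one_when_equidispersed(self, rng):
        y = rng.poisson(5.0, 10_000).astype(float)
        x = rng.standard_normal(10_000)
        fit = fit_glm(y, DesignMatrix({"x": x}), "quasipoisson")
        assert fit.loglik is None
        assert fit.pearson_dispersion == pytest.approx(1.0, abs=0.06)

    def test_support_validation(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="non-negative integer"):
            fit_glm(rng.standard_normal(20), DesignMatrix({"x": x}), "poisson")
        with pytest.raises(ValueError, match="0/1"):
            fit_glm(rng.poisson(3, 20).astype(float), DesignMatrix({"x": x}),
                    "binomial")


class TestNestedSignificance:
    def test_f_equals_squared_t_for_binary_predictor(self, rng):
        group = np.repeat([0.0, 1.0], 15)
        y = rng.standard_normal(30) + 0.4 * group
        sig = nested_significance(_simple_fit(y, group), _null_fit(y))
        t = stats.ttest_ind(y[group == 1], y[group == 0], equal_var=True)
        assert sig.test_kind == "f_test"
        assert sig.p_value == pytest.approx(t.pvalue, abs=1e-12)
        assert sig.statistic == pytest.approx(t.statistic**2, abs=1e-9)

    def test_f_equals_correlation_t_test(self, rng):
        x = rng.standard_normal(50)
        y = 0.2 * x + rng.standard_normal(50)
        sig = nested_significance(_simple_fit(y, x), _null_fit(y))
        assert sig.p_value == pytest.approx(stats.pearsonr(x, y).pvalue, abs=1e-12)

    def test_poisson_lrt_is_twice_loglik_difference(self, rng):
        x = rng.standard_normal(80)
        y = rng.poisson(np.exp(0.5 + 0.2 * x)).astype(float)
        full = fit_glm(y, DesignMatrix({"x": x}), "poisson")
        red = fit_glm(y, DesignMatrix({}), "poisson")
        sig = nested_significance(full, red)
        assert sig.test_kind == "lrt"
        assert sig.statistic == pytest.approx(2 * (full.loglik - red.loglik),
                                              abs=1e-8)

    def test_mismatched_response_rejected(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="same response"):
            nested_significance(_simple_fit(y, x), _null_fit(y + 1.0))


class TestBatchEngines:
    """The vectorized grid engines must agree with the per-dataset fits."""

    def test_gaussian_batch_matches_per_dataset(self, rng):
        Y = rng.standard_normal((5, 30))
        X = rng.gamma(0.5, 2.0, (5, 30))
        res = batch_gaussian_slope_test(Y, X)
        for i in range(5):
            fit = _simple_fit(Y[i], X[i])
            sig = nested_significance(fit, _null_fit(Y[i]))
            assert res["p"][i] == pytest.approx(sig.p_value, abs=1e-10)
            assert res["slope"][i] == pytest.approx(fit.coefficients["x"], abs=1e-10)
            assert res["intercept"][i] == pytest.approx(
                fit.coefficients["intercept"], abs=1e-10
            )

    def test_poisson_batch_matches_statsmodels(self, rng):
        X = rng.standard_normal((5, 60))
        Y = rng.poisson(np.exp(0.3 + 0.2 * X)).astype(float)
        res = batch_poisson_slope_test(Y, X)
        for i in range(5):
            full = fit_glm(Y[i], DesignMatrix({"x": X[i]}), "poisson")
            red = fit_glm(Y[i], DesignMatrix({}), "poisson")
            assert res["b"][i] == pytest.approx(full.coefficients["x"], abs=1e-6)
            sig = nested_significance(full, red)
            assert res["p_lrt"][i] == pytest.approx(sig.p_value, abs=1e-8)
            quasi = fit_glm(Y[i], DesignMatrix({"x": X[i]}), "quasipoisson")
            sig_q = nested_significance(quasi, red)
            assert res["p_quasi"][i] == pytest.approx(sig_q.p_value, abs=1e-6)

    def test_binomial_batch_matches_statsmodels(self, rng):
        X = rng.standard_normal((5, 80))
        Y = (rng.random((5, 80)) < 1 / (1 + np.exp(-0.4 * X))).astype(float)
        res = batch_binomial_slope_test(Y, X)
        for i in range(5):
            full = fit_glm(Y[i], DesignMatrix({"x": X[i]}), "binomial")
            red = fit_glm(Y[i], DesignMatrix({}), "binomial")
            assert res["b"][i] == pytest.approx(full.coefficients["x"], abs=1e-5)
            sig = nested_significance(full, red)
            assert res["p_lrt"][i] == pytest.approx(sig.p_value, abs=1e-7)

    def test_added_predictor_f_matches_nested_ols(self, rng):
        Y = rng.standard_normal((4, 40))
        X_base = rng.standard_normal((4, 40, 3))
        x_focal = rng.gamma(1.0, 2.0, (4, 40))
        res = batch_added_predictor_ftest(Y, X_base, x_focal)
        for i in range(4):
            cols = {f"g{j}": X_base[i, :, j] for j in range(3)}
            full = fit_linear(Y[i], DesignMatrix({**cols, "focal": x_focal[i]}))
            red = fit_linear(Y[i], DesignMatrix(cols))
            sig = nested_significance(full, red)
            assert res["p"][i] == pytest.approx(sig.p_value, abs=1e-9)

    def test_collinear_focal_predictor_flagged_invalid(self, rng):
        Y = rng.standard_normal((2, 30))
        X_base = rng.standard_normal((2, 30, 3))
        res = batch_added_predictor_ftest(Y, X_base, X_base[:, :, 0].copy())
        assert not res["valid"].any()

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(314)
        Y = rng.standard_normal((5000, 20))
        X = rng.standard_normal((5000, 20))
        res = batch_gaussian_slope_test(Y, X)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 1e-3


# frozen reference values computed with lme4 (lmer/glmer, ML / nAGQ=25)
# on the exact datasets reconstructed below
LME4_LMM = dict(intercept=0.75311009, slope=0.00144903, var_u=0.13726353,
                loglik=-87.01115714, lrt=0.00010782)
LME4_OLRE = dict(intercept=0.24282636, slope=0.15239212, var_u=0.31793831,
                 lrt=0.89997662)


def _paired_dataset():
    rng = np.random.default_rng(123)
    groups = np.repeat(np.arange(30), 2)
    x = rng.standard_normal(60)
    u = 0.8 * rng.standard_normal(30)
    y = 0.5 + 0.3 * x + u[groups] + rng.standard_normal(60)
    return y, x, groups


def _olre_dataset():
    rng = np.random.default_rng(456)
    x = rng.standard_normal(50)
    u = 0.7 * rng.standard_normal(50)
    y = rng.poisson(np.exp(0.2 + 0.3 * x + u)).astype(float)
    return y, x


class TestMixedModels:
    def test_gaussian_lmm_matches_lme4_ml_fit(self):
        y, x, groups = _paired_dataset()
        fit = fit_random_intercept(y, DesignMatrix({"x": x}), groups=groups)
        assert fit.coefficients["intercept"] == pytest.approx(
            LME4_LMM["intercept"], abs=1e-5
        )
        assert fit.coefficients["x"] == pytest.approx(LME4_LMM["slope"], abs=1e-5)
        assert fit.random_effect_variance == pytest.approx(LME4_LMM["var_u"],
                                                           abs=1e-3)
        assert fit.loglik == pytest.approx(LME4_LMM["loglik"], abs=1e-5)

    def test_batch_paired_solver_matches_lme4_lrt(self):
        y, x, _ = _paired_dataset()
        res = batch_paired_lmm_slope_lrt(y[None, :], x[None, :], 30)
        assert res["lrt"][0] == pytest.approx(LME4_LMM["lrt"], abs=1e-6)

    def test_batch_paired_solver_matches_mixedlm_under_real_slope(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(np.arange(40), 2)
        x = rng.standard_normal(80)
        y = 0.4 * x + 0.6 * rng.standard_normal(40)[groups] + rng.standard_normal(80)
        res = batch_paired_lmm_slope_lrt(y[None, :], x[None, :], 40)
        full = fit_random_intercept(y, DesignMatrix({"x": x}), groups=groups)
        red = fit_random_intercept(y, DesignMatrix({}), groups=groups)
        sig = nested_significance(full, red)
        assert res["lrt"][0] == pytest.approx(sig.statistic, abs=1e-3)

    def test_poisson_olre_matches_lme4_agq(self):
        y, x = _olre_dataset()
        full = fit_random_intercept(y, DesignMatrix({"x": x}), family="poisson",
                                    olre=True)
        red = fit_random_intercept(y, DesignMatrix({}), family="poisson",
                                   olre=True)
        assert full.coefficients["intercept"] == pytest.approx(
            LME4_OLRE["intercept"], abs=2e-3
        )
        assert full.coefficients["x"] == pytest.approx(LME4_OLRE["slope"], abs=2e-3)
        assert full.random_effect_variance == pytest.approx(LME4_OLRE["var_u"],
                                                            abs=5e-3)
        sig = nested_significance(full, red)
        assert sig.statistic == pytest.approx(LME4_OLRE["lrt"], abs=5e-3)

    def test_olre_variance_boundary_on_equidispersed_counts(self, rng):
        y = rng.poisson(3.0, 200).astype(float)
        x = rng.standard_normal(200)
        fit = fit_random_intercept(y, DesignMatrix({"x": x}), family="poisson",
                                   olre=True)
        assert fit.random_effect_variance < 0.02

    def test_lmm_degrades_to_ols_when_groups_carry_nothing(self, rng):
        x = rng.standard_normal(80)
        y = 0.2 * x + rng.standard_normal(80)  # no group structure at all
        groups = np.repeat(np.arange(40), 2)
        lmm = fit_random_intercept(y, DesignMatrix({"x": x}), groups=groups)
        ols = _simple_fit(y, x)
        assert lmm.loglik == pytest.approx(ols.loglik, abs=1e-3) or \
            lmm.loglik > ols.loglik - 1e-3

    def test_icc_recovery_in_paired_design(self):
        """With a random intercept carrying 30% of the variance, the batch
        solver's ICC estimate averages to 0.3 over replicates."""
        rng = np.random.default_rng(77)
        reps, g = 300, 100
        tau = np.sqrt(0.3 / 0.7)
        base = rng.standard_normal((reps, 2 * g))
        u = tau * rng.standard_normal((reps, g))
        Y = base + np.repeat(u, 2, axis=1)
        X = rng.standard_normal((reps, 2 * g))
        res = batch_paired_lmm_slope_lrt(Y, X, g)
        assert res["icc"].mean() == pytest.approx(0.3, abs=0.03)
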