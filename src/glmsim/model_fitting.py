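"""Model fitting and nested-model significance tests.

Two layers live here. The per-dataset layer (:func:`fit_linear`,
:func:`fit_glm`, :func:`fit_random_intercept`, :func:`nested_significance`)
fits one model at a time, with statsmodels behind the GLM and Gaussian
mixed-model fits and an in-house adaptive Gauss–Hermite maximum-likelihood
fit for the Poisson random-intercept / observation-level-random-effect GLMM
(statsmodels has no Laplace/quadrature Poisson GLMM).

The batch layer (``batch_*`` functions) vectorizes the simple-regression
special cases across tens of thousands of Monte-Carlo replicates at once —
closed-form F tests for Gaussian fits, a batched Newton solver for
single-predictor Poisson/binomial GLMs, batched multi-predictor OLS F tests,
and an exact profiled-likelihood solver for the balanced paired Gaussian
random-intercept model. Each batch path is cross-tested against the
per-dataset layer.

All mixed models are fitted by maximum likelihood (not REML) so likelihood
ratio tests between nested fixed-effect structures are valid; the random
effect is retained in both the full and the reduced model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DesignMatrix",
    "FitResult",
    "SignificanceResult",
    "fit_linear",
    "fit_glm",
    "fit_random_intercept",
    "nested_significance",
    "batch_gaussian_slope_test",
    "batch_poisson_slope_test",
    "batch_binomial_slope_test",
    "batch_added_predictor_ftest",
    "batch_paired_lmm_slope_lrt",
    "batch_poisson_olre_lrt",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class DesignMatrix:
    """Named predictor columns; the intercept is implicit."""

    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(np.asarray(v)) for v in self.columns.values()}
        if len(lengths) > 1:
            raise ValueError("all predictor columns must have equal length")

    @property
    def names(self) -> list[str]:
        return list(self.columns)

    @property
    def k(self) -> int:
        return len(self.columns)

    def n_rows(self, y: np.ndarray) -> int:
        return len(y)

    def matrix(self, n: int) -> np.ndarray:
        """n × (k+1) model matrix with a leading intercept column."""
        cols = [np.ones(n)]
        for v in self.columns.values():
            arr = np.asarray(v, dtype=float)
            if arr.shape != (n,):
                raise ValueError("predictor length does not match response")
            if not np.all(np.isfinite(arr)):
                raise ValueError("design contains non-finite values")
            cols.append(arr)
        return np.column_stack(cols)


@dataclass
class FitResult:
    """A fitted model: coefficients, uncertainty, likelihood and residuals."""

    family: str
    kind: str  # "lm" | "glm" | "lmm" | "glmm"
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    fitted: np.ndarray
    residuals_response: np.ndarray
    residuals_pearson: np.ndarray
    loglik: Optional[float]
    deviance: float
    pearson_dispersion: float
    df_residual: int
    converged: bool
    n: int
    k: int
    y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    model_matrix: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    random_effect_variance: Optional[float] = None
    boundary: bool = False

    @property
    def slope_names(self) -> list[str]:
        return [name for name in self.coefficients if name != "intercept"]


@dataclass(frozen=True)
class SignificanceResult:
    """Nested-model comparison: F test, likelihood ratio test, or the
    dispersion-scaled F test used for quasi-Poisson fits."""

    p_value: float
    statistic: float
    test_kind: str  # "f_test" | "lrt" | "scaled_f"
    df_num: float
    df_den: float  # math.inf for chi-square tests
    valid: bool = True


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        culprits = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                culprits.append(names[j - 1])
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {culprits or names}"
        )


def fit_linear(y: np.ndarray, design: DesignMatrix) -> FitResult:
    """Ordinary least squares with an intercept.

    Coefficients solve the normal equations; the error variance estimate is
    the unbiased RSS/(n−k−1), while the Gaussian log-likelihood uses the ML
    variance RSS/n. With an intercept the response residuals sum to zero.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = design.matrix(n)
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need n > k+1 = {p} observations, got {n}")
    _check_rank(X, design.names)
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(r.T @ r)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    names = ["intercept"] + design.names
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (_LOG2PI + math.log(sigma2_ml) + 1.0)
    pearson = resid / math.sqrt(sigma2) if sigma2 > 0 else resid * 0.0
    return FitResult(
        family="gaussian",
        kind="lm",
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        fitted=fitted,
        residuals_response=resid,
        residuals_pearson=pearson,
        loglik=loglik,
        deviance=rss,
        pearson_dispersion=sigma2 if sigma2 > 0 else 0.0,
        df_residual=df_resid,
        converged=True,
        n=n,
        k=design.k,
        y=y,
        model_matrix=X,
    )


_GLM_FAMILIES = ("gaussian", "poisson", "binomial", "quasipoisson")


def _check_support(y: np.ndarray, family: str) -> None:
    if family in ("poisson", "quasipoisson"):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson family requires non-negative integer response")
    elif family == "binomial":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binomial family requires a 0/1 response")


def fit_glm(y: np.ndarray, design: DesignMatrix, family: str) -> FitResult:
    """GLM with the canonical link (identity/log/logit) via statsmodels IRLS.

    ``quasipoisson`` is a Poisson fit whose dispersion is estimated as
    Pearson χ²/df_residual; its log-likelihood is undefined (None). The
    Gaussian family places no support restriction on y — fitting Gaussian
    models to counts or binary data is exactly the use case under study.
    """
    import statsmodels.api as sm

    if family not in _GLM_FAMILIES:
        raise ValueError(f"family must be one of {_GLM_FAMILIES}")
    y = np.asarray(y, dtype=float)
    _check_support(y, family)
    n = y.size
    X = design.matrix(n)
    _check_rank(X, design.names)
    sm_family = {
        "gaussian": sm.families.Gaussian,
        "poisson": sm.families.Poisson,
        "quasipoisson": sm.families.Poisson,
        "binomial": sm.families.Binomial,
    }[family]()
    res = sm.GLM(y, X, family=sm_family).fit()
    names = ["intercept"] + design.names
    df_resid = n - X.shape[1]
    pearson_disp = float(res.pearson_chi2) / df_resid
    converged = bool(getattr(res, "converged", True))
    mu = np.asarray(res.fittedvalues)
    loglik = None if family == "quasipoisson" else float(res.llf)
    return FitResult(
        family=family,
        kind="glm",
        coefficients=dict(zip(names, np.asarray(res.params).tolist())),
        standard_errors=dict(zip(names, np.asarray(res.bse).tolist())),
        fitted=mu,
        residuals_response=y - mu,
        residuals_pearson=np.asarray(res.resid_pearson),
        loglik=loglik,
        deviance=float(res.deviance),
        pearson_dispersion=pearson_disp,
        df_residual=df_resid,
        converged=converged,
        n=n,
        k=design.k,
        y=y,
        model_matrix=X,
    )


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------


def _poisson_glmm_loglik(
    beta: np.ndarray,
    log_sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    group_start: np.ndarray,
    n_quad: int,
) -> float:
    """Marginal log-likelihood of a Poisson log-link GLMM with one Gaussian
    random intercept, by adaptive Gauss–Hermite quadrature per group.

    The integrand mode per group is found by Newton steps (the per-group
    problem is one-dimensional and strictly concave), nodes are centred and
    scaled at the mode — the K=1 special case is the Laplace approximation.
    """
    sigma = math.exp(log_sigma)
    eta = X @ beta
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    n_groups = group_start.size - 1
    counts = np.diff(group_start)
    gid = np.repeat(np.arange(n_groups), counts)
    sum_y = np.bincount(gid, weights=y, minlength=n_groups)

    u = np.zeros(n_groups)
    for _ in range(50):
        lam = np.exp(np.clip(eta + u[gid], -700, 700))
        g1 = sum_y - np.bincount(gid, weights=lam, minlength=n_groups) - u / sigma**2
        g2 = -np.bincount(gid, weights=lam, minlength=n_groups) - 1.0 / sigma**2
        step = g1 / g2
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    lam = np.exp(np.clip(eta + u[gid], -700, 700))
    hess = np.bincount(gid, weights=lam, minlength=n_groups) + 1.0 / sigma**2
    s = 1.0 / np.sqrt(hess)

    # log f(u_g + s_g t_k) for every node, relative to the mode
    log_gauss_const = -math.log(sigma) - 0.5 * _LOG2PI
    vals = np.empty((n_quad, n_groups))
    for k_i, t in enumerate(nodes):
        uk = u + s * t
        etak = np.clip(eta + uk[gid], -700, 700)
        contrib = np.bincount(gid, weights=y * etak - np.exp(etak), minlength=n_groups)
        vals[k_i] = contrib - 0.5 * uk**2 / sigma**2 + 0.5 * t * t
    m = vals.max(axis=0)
    integ = (weights[:, None] * np.exp(vals - m)).sum(axis=0)
    log_int = m + np.log(integ) + np.log(s)
    const = -special.gammaln(y + 1.0).sum()
    return float((log_int + log_gauss_const).sum() + const)


def _fit_poisson_glmm(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_quad: int = 25
) -> tuple[np.ndarray, float, float, bool]:
    """Maximize the AGQ marginal likelihood over (β, log σ).

    Returns (beta, sigma2, loglik, converged). The variance is bounded below
    (log σ ≥ −8), which acts as the boundary at σ² → 0.
    """
    order = np.argsort(groups, kind="stable")
    y_s, X_s, g_s = y[order], X[order], groups[order]
    _, start_idx = np.unique(g_s, return_index=True)
    group_start = np.append(start_idx, y_s.size)

    # starting values from the fixed-effect Poisson fit
    beta0 = np.zeros(X.shape[1])
    beta0[0] = math.log(max(y.mean(), 1e-3))
    theta0 = np.append(beta0, math.log(0.5))

    def neg(theta: np.ndarray) -> float:
        return -_poisson_glmm_loglik(
            theta[:-1], theta[-1], y_s, X_s, group_start, n_quad
        )

    bounds = [(None, None)] * X.shape[1] + [(-8.0, 5.0)]
    res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds)
    beta = res.x[:-1]
    sigma2 = math.exp(2.0 * res.x[-1])
    return beta, sigma2, -float(res.fun), bool(res.success)


def fit_random_intercept(
    y: np.ndarray,
    design: DesignMatrix,
    groups: Optional[np.ndarray] = None,
    family: str = "gaussian",
    olre: bool = False,
    n_quad: int = 25,
) -> FitResult:
    """Random-intercept mixed model, fitted by maximum likelihood.

    Gaussian responses go through statsmodels MixedLM (ML, not REML, so
    likelihood ratio tests between nested fixed-effect structures are valid).
    Poisson responses use the in-house adaptive Gauss–Hermite ML fit; with
    ``olre=True`` every row gets its own random intercept (an
    observation-level random effect absorbing extra-Poisson dispersion,
    i.e. a Poisson-lognormal model). Variance estimates at the boundary
    (σ² ≈ 0) set ``boundary`` but are never dropped silently.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if olre:
        groups = np.arange(n)
    if groups is None:
        raise ValueError("groups required unless olre=True")
    groups = np.asarray(groups)
    if not olre and np.unique(groups).size < 2:
        raise ValueError("need at least 2 groups")
    X = design.matrix(n)
    _check_rank(X, design.names)
    names = ["intercept"] + design.names

    if family == "gaussian":
        import statsmodels.api as sm

        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=False)
        beta = np.asarray(res.fe_params)
        re_var = float(np.asarray(res.cov_re)[0, 0])
        fitted = X @ beta
        resid = y - fitted
        sigma2 = float(res.scale)
        return FitResult(
            family="gaussian",
            kind="lmm",
            coefficients=dict(zip(names, beta.tolist())),
            standard_errors=dict(zip(names, np.asarray(res.bse_fe).tolist())),
            fitted=fitted,
            residuals_response=resid,
            residuals_pearson=resid / math.sqrt(sigma2),
            loglik=float(res.llf),
            deviance=-2.0 * float(res.llf),
            pearson_dispersion=sigma2,
            df_residual=n - X.shape[1],
            converged=bool(res.converged),
            n=n,
            k=design.k,
            y=y,
            model_matrix=X,
            random_effect_variance=re_var,
            boundary=re_var < 1e-6,
        )
    if family == "poisson":
        _check_support(y, "poisson")
        beta, sigma2, loglik, converged = _fit_poisson_glmm(y, X, groups, n_quad)
        fitted = np.exp(np.clip(X @ beta + sigma2 / 2.0, -700, 700))
        resid = y - fitted
        return FitResult(
            family="poisson",
            kind="glmm",
            coefficients=dict(zip(names, beta.tolist())),
            standard_errors={name: math.nan for name in names},
            fitted=fitted,
            residuals_response=resid,
            residuals_pearson=resid / np.sqrt(np.clip(fitted, 1e-300, None)),
            loglik=loglik,
            deviance=-2.0 * loglik,
            pearson_dispersion=math.nan,
            df_residual=n - X.shape[1],
            converged=converged,
            n=n,
            k=design.k,
            y=y,
            model_matrix=X,
            random_effect_variance=sigma2,
            boundary=sigma2 < 1e-6,
        )
    raise ValueError("family must be 'gaussian' or 'poisson' for mixed models")


# ---------------------------------------------------------------------------
# nested-model significance
# ---------------------------------------------------------------------------


def nested_significance(full: FitResult, reduced: FitResult) -> SignificanceResult:
    """Test the predictors present in ``full`` but not in ``reduced``.

    Gaussian fixed-effect fits use the exact F test on residual sums of
    squares; quasi-Poisson uses the deviance-difference F test scaled by the
    full model's Pearson dispersion; everything else (Poisson/binomial GLMs
    and all ML mixed models) uses the χ² likelihood ratio test.
    """
    if full.y is None or reduced.y is None or not np.array_equal(full.y, reduced.y):
        raise ValueError("full and reduced models must be fitted to the same response")
    full_names = set(full.coefficients)
    red_names = set(reduced.coefficients)
    if not red_names <= full_names:
        raise ValueError("reduced model's predictors must nest within the full model")
    df_num = len(full_names) - len(red_names)
    if df_num < 1:
        raise ValueError("full model adds no predictors over the reduced model")
    if not (full.converged and reduced.converged):
        return SignificanceResult(math.nan, math.nan, "lrt", df_num, math.inf,
                                  valid=False)

    if full.family == "gaussian" and full.kind in ("lm", "glm"):
        rss_full = full.deviance
        rss_red = reduced.deviance
        df_den = full.df_residual
        if rss_full <= 0:
            return SignificanceResult(math.nan, math.nan, "f_test", df_num, df_den,
                                      valid=False)
        f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
        p = float(stats.f.sf(f, df_num, df_den))
        return SignificanceResult(p, float(f), "f_test", df_num, df_den)
    if full.family == "quasipoisson":
        ddev = reduced.deviance - full.deviance
        disp = full.pearson_dispersion
        df_den = full.df_residual
        if disp <= 0:
            return SignificanceResult(math.nan, math.nan, "scaled_f", df_num, df_den,
                                      valid=False)
        f = (ddev / df_num) / disp
        p = float(stats.f.sf(f, df_num, df_den))
        return SignificanceResult(p, float(f), "scaled_f", df_num, df_den)
    # likelihood ratio test
    if full.loglik is None or reduced.loglik is None:
        raise ValueError("likelihood ratio test requires log-likelihoods")
    lrt = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, df_num))
    return SignificanceResult(p, lrt, "lrt", df_num, math.inf)


# ---------------------------------------------------------------------------
# batch engines (vectorized across Monte-Carlo replicates)
# ---------------------------------------------------------------------------


def batch_gaussian_slope_test(Y: np.ndarray, X: np.ndarray) -> dict[str, np.ndarray]:
    """Gaussian simple regression, all replicates at once.

    Row r of ``Y``/``X`` is one dataset. Returns the slope F-test p-value
    (identical to the nested RSS F test and to the square-of-t test), the
    sample correlation, slope and intercept, plus a validity mask: rows with
    a constant predictor or a perfectly-fitted/constant response have no
    defined F statistic and are flagged invalid.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc**2).sum(axis=1)
    syy = (Yc**2).sum(axis=1)
    sxy = (Xc * Yc).sum(axis=1)
    valid = (sxx > 0) & (syy > 0)
    safe_sxx = np.where(sxx > 0, sxx, 1.0)
    r = np.where(valid, sxy / np.sqrt(np.where(valid, sxx * syy, 1.0)), 0.0)
    r = np.clip(r, -1.0, 1.0)
    one_minus_r2 = 1.0 - r**2
    valid &= one_minus_r2 > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        f = r**2 * (n - 2) / np.where(one_minus_r2 > 0, one_minus_r2, np.inf)
    p = stats.f.sf(f, 1, n - 2)
    slope = sxy / safe_sxx
    intercept = Y.mean(axis=1) - slope * X.mean(axis=1)
    return {"p": p, "r": r, "slope": slope, "intercept": intercept, "valid": valid}


def _batch_newton_glm(
    Y: np.ndarray,
    X: np.ndarray,
    kind: str,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Newton–Raphson for single-predictor canonical-link GLMs.

    Returns (a, b, converged, valid) for the linear predictor a + b·x with a
    log link (kind="poisson") or logit link (kind="binomial").
    """
    reps = Y.shape[0]
    ybar = Y.mean(axis=1)
    if kind == "poisson":
        valid = ybar > 0
        a = np.where(valid, np.log(np.clip(ybar, 1e-300, None)), 0.0)
    else:
        valid = (ybar > 0) & (ybar < 1)
        pbar = np.clip(ybar, 1e-12, 1 - 1e-12)
        a = np.log(pbar / (1 - pbar))
    b = np.zeros(reps)
    delta = np.full(reps, np.inf)
    for _ in range(max_iter):
        eta = np.clip(a[:, None] + b[:, None] * X, -30.0, 30.0)
        if kind == "poisson":
            mu = np.exp(eta)
            w = mu
        else:
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
        s0 = (Y - mu).sum(axis=1)
        s1 = ((Y - mu) * X).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * X).sum(axis=1)
        i11 = (w * X * X).sum(axis=1)
        det = i00 * i11 - i01 * i01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (i11 * s0 - i01 * s1) / det
        db = (-i01 * s0 + i00 * s1) / det
        da = np.clip(da, -5.0, 5.0)
        db = np.clip(db, -5.0, 5.0)
        a += da
        b += db
        delta = np.maximum(np.abs(da), np.abs(db))
        if delta.max() < tol:
            break
    converged = delta < 1e-6
    return a, b, converged, valid


def batch_poisson_slope_test(Y: np.ndarray, X: np.ndarray) -> dict[str, np.ndarray]:
    """Single-predictor Poisson GLM per row: χ² LRT against the null model
    and the dispersion-scaled (quasi-Poisson) F test from the same fit.

    The null fit is closed form (intercept = log ȳ). The quasi-Poisson test
    scales the deviance difference by Pearson χ²/df of the full model and
    refers it to F(1, n−2). Coefficient estimates are shared: quasi-Poisson
    changes inference, never the fit.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = Y.shape[1]
    a, b, converged, valid = _batch_newton_glm(Y, X, "poisson")
    valid &= X.std(axis=1) > 0
    eta = np.clip(a[:, None] + b[:, None] * X, -30.0, 30.0)
    mu = np.exp(eta)
    ll_full = (Y * eta - mu).sum(axis=1)
    ybar = np.clip(Y.mean(axis=1), 1e-300, None)
    ll_null = (Y * np.log(ybar)[:, None] - ybar[:, None]).sum(axis=1)
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    p_lrt = stats.chi2.sf(lrt, 1)
    dispersion = ((Y - mu) ** 2 / np.clip(mu, 1e-300, None)).sum(axis=1) / (n - 2)
    f = lrt / np.clip(dispersion, 1e-300, None)
    p_quasi = stats.f.sf(f, 1, n - 2)
    ok = valid & converged
    return {
        "p_lrt": p_lrt,
        "p_quasi": p_quasi,
        "a": a,
        "b": b,
        "dispersion": dispersion,
        "converged": converged,
        "valid": ok,
    }


def batch_binomial_slope_test(Y: np.ndarray, X: np.ndarray) -> dict[str, np.ndarray]:
    """Single-predictor Bernoulli logistic GLM per row, χ² LRT on the slope."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    a, b, converged, valid = _batch_newton_glm(Y, X, "binomial")
    valid &= X.std(axis=1) > 0
    eta = np.clip(a[:, None] + b[:, None] * X, -30.0, 30.0)
    ll_full = (Y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    ybar = np.clip(Y.mean(axis=1), 1e-12, 1 - 1e-12)
    ll_null = Y.shape[1] * (
        ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar)
    )
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    p_lrt = stats.chi2.sf(lrt, 1)
    ok = valid & converged
    return {"p_lrt": p_lrt, "a": a, "b": b, "converged": converged, "valid": ok}


def batch_added_predictor_ftest(
    Y: np.ndarray, X_base: np.ndarray, x_focal: np.ndarray
) -> dict[str, np.ndarray]:
    """F test for one focal predictor added to a base OLS model, batched.

    ``Y`` is (reps, n), ``X_base`` (reps, n, k) holds the always-included
    predictors (no intercept column — it is added here), ``x_focal``
    (reps, n) the tested predictor. Rows whose full design is numerically
    singular (e.g. a focal predictor duplicating a base column) are flagged
    invalid rather than raised, so one bad replicate cannot abort a cell.
    """
    Y = np.asarray(Y, dtype=float)
    reps, n = Y.shape
    ones = np.ones((reps, n, 1))
    Xr = np.concatenate([ones, X_base], axis=2)
    Xf = np.concatenate([Xr, x_focal[..., None]], axis=2)
    p_red = Xr.shape[2]
    p_full = Xf.shape[2]

    def rss(Xd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xtx = np.einsum("rni,rnj->rij", Xd, Xd)
        xty = np.einsum("rni,rn->ri", Xd, Y)
        diag_scale = np.abs(np.prod(np.einsum("rii->ri", xtx), axis=1))
        ok = np.abs(np.linalg.det(xtx)) > 1e-10 * np.clip(diag_scale, 1e-300, None)
        beta = np.zeros_like(xty)
        if ok.any():
            beta[ok] = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
        resid = Y - np.einsum("rni,ri->rn", Xd, beta)
        return (resid**2).sum(axis=1), ok

    rss_red, ok_r = rss(Xr)
    rss_full, ok_f = rss(Xf)
    valid = ok_r & ok_f & (rss_full > 0)
    df_den = n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / (p_full - p_red)) / (rss_full / df_den)
    p = stats.f.sf(np.where(valid, f, 0.0), p_full - p_red, df_den)
    return {"p": p, "f": f, "valid": valid}


def _paired_lmm_profile_nll(
    lam: np.ndarray,
    sy: np.ndarray,
    dy: np.ndarray,
    sx: np.ndarray,
    dx: np.ndarray,
    with_slope: bool,
) -> np.ndarray:
    """−2·profile-loglik (up to constants) of the paired random-intercept
    model at between-pair variance ratio ``lam`` = 2σ_u²/σ_e², per replicate.

    Uses the orthogonal pair decomposition: sums s=(y₁+y₂)/√2 carry variance
    σ_e²(1+λ) and an intercept column √2; differences d=(y₁−y₂)/√2 carry
    variance σ_e² and no intercept. β and σ_e² are profiled in closed form.
    """
    reps, g = sy.shape
    w = 1.0 / (1.0 + lam)[:, None]
    if with_slope:
        a11 = 2.0 * g * w[:, 0]
        a12 = math.sqrt(2.0) * (w * sx).sum(axis=1)
        a22 = (w * sx * sx).sum(axis=1) + (dx * dx).sum(axis=1)
        b1 = math.sqrt(2.0) * (w * sy).sum(axis=1)
        b2 = (w * sx * sy).sum(axis=1) + (dx * dy).sum(axis=1)
        det = np.clip(a11 * a22 - a12 * a12, 1e-300, None)
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (-a12 * b1 + a11 * b2) / det
        res_s = sy - math.sqrt(2.0) * beta0[:, None] - beta1[:, None] * sx
        res_d = dy - beta1[:, None] * dx
    else:
        a11 = 2.0 * g * w[:, 0]
        b1 = math.sqrt(2.0) * (w * sy).sum(axis=1)
        beta0 = b1 / a11
        res_s = sy - math.sqrt(2.0) * beta0[:, None]
        res_d = dy
    rssw = (w * res_s**2).sum(axis=1) + (res_d**2).sum(axis=1)
    sigma2 = np.clip(rssw / (2.0 * g), 1e-300, None)
    return 2.0 * g * np.log(sigma2) + g * np.log1p(lam)


def batch_paired_lmm_slope_lrt(
    Y: np.ndarray, X: np.ndarray, n_groups: int
) -> dict[str, np.ndarray]:
    """Exact-ML likelihood ratio test of the slope in a balanced paired
    Gaussian random-intercept model, vectorized across replicates.

    Rows of ``Y``/``X`` hold ``n_groups`` consecutive pairs (2 observations
    per group). The variance ratio is profiled out analytically and the
    remaining one-dimensional likelihood in λ = 2σ_u²/σ_e² is maximized by
    golden-section search on log(1+λ), separately for the full and the
    slope-free model; the LRT statistic is referred to χ²₁. Also returns the
    full model's intraclass-correlation estimate λ/(λ+2).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    reps = Y.shape[0]
    yp = Y.reshape(reps, n_groups, 2)
    xp = X.reshape(reps, n_groups, 2)
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    sy = (yp[..., 0] + yp[..., 1]) * inv_sqrt2
    dy = (yp[..., 0] - yp[..., 1]) * inv_sqrt2
    sx = (xp[..., 0] + xp[..., 1]) * inv_sqrt2
    dx = (xp[..., 0] - xp[..., 1]) * inv_sqrt2

    def minimize(with_slope: bool) -> tuple[np.ndarray, np.ndarray]:
        # golden section on t = log(1+lambda) in [0, 8]
        lo = np.zeros(reps)
        hi = np.full(reps, 8.0)
        gr = (math.sqrt(5.0) - 1.0) / 2.0
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc = _paired_lmm_profile_nll(np.expm1(c), sy, dy, sx, dx, with_slope)
        fd = _paired_lmm_profile_nll(np.expm1(d), sy, dy, sx, dx, with_slope)
        for _ in range(60):
            less = fc < fd
            hi = np.where(less, d, hi)
            lo = np.where(less, lo, c)
            c = hi - gr * (hi - lo)
            d = lo + gr * (hi - lo)
            fc = _paired_lmm_profile_nll(np.expm1(c), sy, dy, sx, dx, with_slope)
            fd = _paired_lmm_profile_nll(np.expm1(d), sy, dy, sx, dx, with_slope)
        t = np.where(fc < fd, c, d)
        nll = np.minimum(fc, fd)
        # check the sigma_u = 0 boundary explicitly
        f0 = _paired_lmm_profile_nll(np.zeros(reps), sy, dy, sx, dx, with_slope)
        at0 = f0 <= nll
        return np.where(at0, 0.0, np.expm1(t)), np.where(at0, f0, nll)

    lam_full, nll_full = minimize(True)
    _, nll_red = minimize(False)
    lrt = np.clip(nll_red - nll_full, 0.0, None)
    p = stats.chi2.sf(lrt, 1)
    valid = X.var(axis=1) > 0
    icc = lam_full / (lam_full + 2.0)
    return {"p": p, "lrt": lrt, "icc": icc, "lambda": lam_full, "valid": valid}


def batch_poisson_olre_lrt(
    Y: np.ndarray, X: np.ndarray, n_quad: int = 21
) -> dict[str, np.ndarray]:
    """Slope LRT for the Poisson GLMM with an observation-level random
    effect, one replicate at a time (the AGQ fit does not vectorize across
    replicates). Both the full and the null model retain the random effect.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    reps, n = Y.shape
    groups = np.arange(n)
    p = np.full(reps, np.nan)
    sigma2 = np.full(reps, np.nan)
    converged = np.zeros(reps, dtype=bool)
    ones = np.ones(n)
    for i in range(reps):
        y = Y[i]
        if y.max() == 0 or X[i].std() == 0:
            continue
        Xf = np.column_stack([ones, X[i]])
        Xr = ones[:, None]
        try:
            bf, s2f, llf, cf = _fit_poisson_glmm(y, Xf, groups, n_quad)
            br, s2r, llr, cr = _fit_poisson_glmm(y, Xr, groups, n_quad)
        except Exception:
            continue
        if not (cf and cr):
            continue
        lrt = max(2.0 * (llf - llr), 0.0)
        p[i] = stats.chi2.sf(lrt, 1)
        sigma2[i] = s2f
        converged[i] = True
    return {"p": p, "sigma2": sigma2, "valid": converged}
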