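"""Scenario grids: configuration, seeding, execution, tidy output.

Five experiment families are provided, each sweeping distribution pairs
(dependent variable Y × predictor X) over Monte-Carlo replicates:

* :func:`run_type1_grid` — no effect simulated; the rejection rate of the
  slope test estimates the type-I error rate, together with the scale shift
  υ and tail fold-biases of −log₁₀(p).
* :func:`run_power_grid` — a target correlation is induced by calibrated
  rank matching; reports power, slope bias (mean) and precision (CV).
* :func:`run_lmm_grid` — null grid for the Gaussian random-intercept model
  (paired design, random effect carrying ≈30% of the variance).
* :func:`run_multivariate_grid` — null grid for one focal predictor added to
  three Gaussian predictors.
* :func:`run_family_grid` — error-structure comparison: either the null
  ("misspecification") mode fitting Gaussian/quasi-Poisson/OLRE-GLMM/Poisson
  models to discrete data, or the "power_comparison" mode fitting Gaussian
  vs. matched error structures to data with an induced effect.

Every cell draws from its own deterministic random stream derived from
(base_seed, cell coordinates), so results are reproducible under any
execution order and cells parallelize embarrassingly (``n_jobs``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .distributions import (
    DistributionSpec,
    PRESET_IDS,
    preset,
    sample_matrix,
    spec_from_config,
)
from .effect_induction import (
    EffectCalibration,
    calibrate_intermediate_correlation,
    sample_correlated_matrix,
)
from .model_fitting import (
    batch_added_predictor_ftest,
    batch_binomial_slope_test,
    batch_gaussian_slope_test,
    batch_paired_lmm_slope_lrt,
    batch_poisson_olre_lrt,
    batch_poisson_slope_test,
)
from .pvalue_metrics import (
    required_effect_for_power,
    summarize_pvalues,
)

__all__ = [
    "DEFAULT_ALPHAS",
    "DEFAULT_N_OBS",
    "cell_rng",
    "design_effect",
    "load_config",
    "run_family_grid",
    "run_lmm_grid",
    "run_multivariate_grid",
    "run_power_grid",
    "run_type1_grid",
    "write_grid",
]

DEFAULT_ALPHAS: tuple[float, ...] = (0.05, 0.001, 0.0001)
DEFAULT_N_OBS: tuple[int, ...] = (10, 25, 50, 100, 250, 500, 1000)

#: replicate-block size cap (elements per matrix) to bound memory
_BLOCK_ELEMS = 5_000_000

_COLUMNS = [
    "scenario", "dist_y", "dist_x", "n_obs", "model_spec", "target_r",
    "alpha", "metric", "value", "mc_se", "n_replicates", "n_failed",
]


def cell_rng(base_seed: int, *parts: object) -> np.random.Generator:
    """Deterministic per-cell generator from a stable 31-bit hash of the
    cell coordinates combined with the base seed."""
    key = "|".join(repr(p) for p in parts).encode()
    h = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), h]))


def _resolve_spec(d: Union[str, DistributionSpec, dict]) -> DistributionSpec:
    if isinstance(d, DistributionSpec):
        return d
    if isinstance(d, str):
        return preset(d)
    return spec_from_config(d)


def _blocks(replicates: int, n: int) -> Iterable[int]:
    per_block = max(1, _BLOCK_ELEMS // max(n, 1))
    remaining = replicates
    while remaining > 0:
        b = min(per_block, remaining)
        yield b
        remaining -= b


def _rows(
    scenario: str,
    dist_y: str,
    dist_x: str,
    n_obs: int,
    model_spec: str,
    target_r: float,
    summary,
    extra: Optional[dict[str, float]] = None,
) -> list[dict]:
    base = dict(
        scenario=scenario, dist_y=dist_y, dist_x=dist_x, n_obs=n_obs,
        model_spec=model_spec, target_r=target_r,
        n_replicates=summary.n_replicates, n_failed=summary.n_failed,
    )
    rate_name = "type1_rate" if target_r == 0.0 else "power"
    out = []
    for alpha, (rate, mc_se) in summary.rates.items():
        out.append({**base, "alpha": alpha, "metric": rate_name,
                    "value": rate, "mc_se": mc_se})
    if summary.scale_shift_upsilon is not None:
        out.append({**base, "alpha": np.nan, "metric": "scale_shift",
                    "value": summary.scale_shift_upsilon, "mc_se": np.nan})
    for expo, bias in summary.logp_bias.items():
        out.append({**base, "alpha": np.nan, "metric": f"logp_bias_{expo:g}",
                    "value": bias, "mc_se": np.nan})
    if summary.slope_mean is not None:
        out.append({**base, "alpha": np.nan, "metric": "slope_mean",
                    "value": summary.slope_mean, "mc_se": np.nan})
        out.append({**base, "alpha": np.nan, "metric": "slope_cv",
                    "value": summary.slope_cv, "mc_se": np.nan})
    for name, value in (extra or {}).items():
        out.append({**base, "alpha": np.nan, "metric": name,
                    "value": value, "mc_se": np.nan})
    return out


def _skip_row(
    scenario: str, dist_y: str, dist_x: str, n_obs: int, model_spec: str,
    target_r: float, reason: str,
) -> dict:
    return dict(
        scenario=scenario, dist_y=dist_y, dist_x=dist_x, n_obs=n_obs,
        model_spec=model_spec, target_r=target_r, alpha=np.nan,
        metric=f"skipped:{reason}", value=np.nan, mc_se=np.nan,
        n_replicates=0, n_failed=0,
    )


def _finish(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


def _map_cells(cell_fn, cells: Sequence, n_jobs: int = 1) -> list:
    if n_jobs == 1:
        return [cell_fn(c) for c in cells]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(delayed(cell_fn)(c) for c in cells)


def _null_cell_pvalues(
    spec_y: DistributionSpec,
    spec_x: DistributionSpec,
    n: int,
    replicates: int,
    rng: np.random.Generator,
    model: str,
) -> tuple[np.ndarray, int]:
    """p-values of the slope test under independence, chunked over blocks."""
    ps: list[np.ndarray] = []
    n_failed = 0
    for block in _blocks(replicates, n):
        Y = sample_matrix(spec_y, (block, n), rng)
        X = sample_matrix(spec_x, (block, n), rng)
        if model == "gaussian_lm":
            res = batch_gaussian_slope_test(Y, X)
            p, ok = res["p"], res["valid"]
        elif model in ("poisson_glm", "quasipoisson_glm"):
            res = batch_poisson_slope_test(Y, X)
            p = res["p_lrt"] if model == "poisson_glm" else res["p_quasi"]
            ok = res["valid"]
        elif model == "binomial_glm":
            res = batch_binomial_slope_test(Y, X)
            p, ok = res["p_lrt"], res["valid"]
        elif model == "poisson_olre_glmm":
            res = batch_poisson_olre_lrt(Y, X)
            p, ok = res["p"], res["valid"]
        else:
            raise ValueError(f"unknown model_spec {model!r}")
        ps.append(p[ok])
        n_failed += int(block - ok.sum())
    return np.concatenate(ps), n_failed


def run_type1_grid(
    dist_y: Optional[Sequence] = None,
    dist_x: Optional[Sequence] = None,
    n_obs: Sequence[int] = DEFAULT_N_OBS,
    replicates: int = 50_000,
    base_seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    model: str = "gaussian_lm",
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Null grid over distribution pairs: type-I error rates, υ, tail biases.

    Y and X are drawn independently (no coupling step); the slope test is the
    exact F test for the Gaussian linear model or the model's LRT otherwise.
    Replicates with degenerate data (constant predictor or perfectly fitted
    response) are dropped and counted in ``n_failed``.
    """
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    ys = [_resolve_spec(d) for d in (dist_y or PRESET_IDS)]
    xs = [_resolve_spec(d) for d in (dist_x or PRESET_IDS)]
    cells = [(sy, sx, n) for sy in ys for sx in xs for n in n_obs]

    def one(cell):
        sy, sx, n = cell
        rng = cell_rng(base_seed, "type1", sy.label(), sx.label(), n, model, 0.0)
        p, n_failed = _null_cell_pvalues(sy, sx, n, replicates, rng, model)
        if p.size < replicates / 2:
            return [_skip_row("type1", sy.label(), sx.label(), n, model, 0.0,
                              "more than half of replicates degenerate")]
        summary = summarize_pvalues(p, tuple(alphas), n_failed=n_failed)
        return _rows("type1", sy.label(), sx.label(), n, model, 0.0, summary)

    rows: list[dict] = []
    for chunk in _map_cells(one, cells, n_jobs):
        rows.extend(chunk)
    return _finish(rows)


def design_effect(n: int, target_power: float = 0.5, alpha: float = 0.05) -> float:
    """Effect size giving the target power for Gaussian data at sample size n,
    rounded to the study's reporting precision (2 decimals, 3 for n ≥ 1000)."""
    return required_effect_for_power(
        n, target_power, alpha, round_digits=3 if n >= 1000 else 2
    )


def run_power_grid(
    dist_y: Optional[Sequence] = None,
    dist_x: Optional[Sequence] = None,
    n_obs: Sequence[int] = (10, 100, 1000),
    target_r: Union[str, float] = "power50",
    replicates: int = 50_000,
    base_seed: int = 0,
    alphas: Sequence[float] = (0.05, 0.001),
    calib_n: int = 200_000,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Power/bias/precision grid with an induced effect.

    ``target_r`` is either a fixed correlation or ``"power50"``, which picks
    per sample size the effect giving 50% power under Gaussian data. Y and X
    are z-standardized per replicate, so the fitted slope equals the sample
    correlation and its expected value equals the induced effect. Cells whose
    calibration cannot reach the target (marginals too constrained, e.g.
    Bernoulli(0.9) with gamma(0.1)) are skipped with a reason row.
    """
    ys = [_resolve_spec(d) for d in (dist_y or PRESET_IDS)]
    xs = [_resolve_spec(d) for d in (dist_x or PRESET_IDS)]
    cells = [(sy, sx, n) for sy in ys for sx in xs for n in n_obs]

    def one(cell):
        sy, sx, n = cell
        r0 = design_effect(n) if target_r == "power50" else float(target_r)
        rng = cell_rng(base_seed, "power", sy.label(), sx.label(), n, "gaussian_lm", r0)
        calib = calibrate_intermediate_correlation(
            sy, sx, r0, n=n, calib_n=calib_n,
            seed=int(rng.integers(2**31)),
        )
        if not calib.converged:
            return [_skip_row("power", sy.label(), sx.label(), n, "gaussian_lm",
                              r0, "effect not attainable for these marginals")]
        ps, slopes = [], []
        n_failed = 0
        for block in _blocks(replicates, n):
            Y, X = sample_correlated_matrix(calib, n, block, rng, standardize=True)
            res = batch_gaussian_slope_test(Y, X)
            ok = res["valid"]
            ps.append(res["p"][ok])
            slopes.append(res["slope"][ok])
            n_failed += int(block - ok.sum())
        p = np.concatenate(ps)
        if p.size < replicates / 2:
            return [_skip_row("power", sy.label(), sx.label(), n, "gaussian_lm",
                              r0, "more than half of replicates degenerate")]
        summary = summarize_pvalues(
            p, tuple(alphas), slopes=np.concatenate(slopes), n_failed=n_failed
        )
        return _rows("power", sy.label(), sx.label(), n, "gaussian_lm", r0, summary,
                     extra={"achieved_r_calibration": calib.achieved_r})

    rows: list[dict] = []
    for chunk in _map_cells(one, cells, n_jobs):
        rows.extend(chunk)
    return _finish(rows)


def run_lmm_grid(
    dist_y: Optional[Sequence] = None,
    dist_x: Optional[Sequence] = None,
    n_groups: int = 100,
    icc: float = 0.3,
    replicates: int = 50_000,
    base_seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Null grid for the Gaussian random-intercept model.

    Each replicate has ``n_groups`` samples measured twice. The response is a
    per-replicate standardized draw from the Y distribution plus a Gaussian
    group intercept with variance icc/(1−icc), so the random effect carries a
    fraction ``icc`` (default 30%) of the response variance. Significance of
    the (null) slope is a χ² LRT between ML fits with the random effect
    retained in both models.
    """
    ys = [_resolve_spec(d) for d in (dist_y or PRESET_IDS)]
    xs = [_resolve_spec(d) for d in (dist_x or PRESET_IDS)]
    n = 2 * n_groups
    tau = float(np.sqrt(icc / (1.0 - icc)))
    cells = [(sy, sx) for sy in ys for sx in xs]

    def one(cell):
        sy, sx = cell
        rng = cell_rng(base_seed, "lmm", sy.label(), sx.label(), n_groups, icc)
        ps, iccs = [], []
        n_failed = 0
        for block in _blocks(replicates, n):
            base = sample_matrix(sy, (block, n), rng)
            mu = base.mean(axis=1, keepdims=True)
            sd = base.std(axis=1, ddof=1, keepdims=True)
            ok0 = (sd > 0).ravel()
            base = np.where(ok0[:, None], (base - mu) / np.where(sd > 0, sd, 1.0), base)
            u = tau * rng.standard_normal((block, n_groups))
            Y = base + np.repeat(u, 2, axis=1)
            X = sample_matrix(sx, (block, n), rng)
            res = batch_paired_lmm_slope_lrt(Y, X, n_groups)
            ok = res["valid"] & ok0
            ps.append(res["p"][ok])
            iccs.append(res["icc"][ok])
            n_failed += int(block - ok.sum())
        p = np.concatenate(ps)
        if p.size < replicates / 2:
            return [_skip_row("lmm_null", sy.label(), sx.label(), n, "gaussian_lmm",
                              0.0, "more than half of replicates degenerate")]
        summary = summarize_pvalues(p, tuple(alphas), n_failed=n_failed)
        return _rows("lmm_null", sy.label(), sx.label(), n, "gaussian_lmm", 0.0,
                     summary,
                     extra={"icc_mean": float(np.concatenate(iccs).mean())})

    rows: list[dict] = []
    for chunk in _map_cells(one, cells, n_jobs):
        rows.extend(chunk)
    return _finish(rows)


def run_multivariate_grid(
    dist_y: Optional[Sequence] = None,
    dist_x: Optional[Sequence] = None,
    n_obs: int = 100,
    replicates: int = 50_000,
    base_seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Null grid for one focal predictor among three Gaussian predictors.

    The model with all four predictors is compared against the three-predictor
    model by the exact F test; the focal predictor follows the X distribution
    of the cell and carries no effect.
    """
    ys = [_resolve_spec(d) for d in (dist_y or PRESET_IDS)]
    xs = [_resolve_spec(d) for d in (dist_x or PRESET_IDS)]
    cells = [(sy, sx) for sy in ys for sx in xs]

    def one(cell):
        sy, sx = cell
        rng = cell_rng(base_seed, "multivariate", sy.label(), sx.label(), n_obs)
        ps = []
        n_failed = 0
        for block in _blocks(replicates, 4 * n_obs):
            Y = sample_matrix(sy, (block, n_obs), rng)
            X_base = rng.standard_normal((block, n_obs, 3))
            x_focal = sample_matrix(sx, (block, n_obs), rng)
            res = batch_added_predictor_ftest(Y, X_base, x_focal)
            ok = res["valid"]
            ps.append(res["p"][ok])
            n_failed += int(block - ok.sum())
        p = np.concatenate(ps)
        if p.size < replicates / 2:
            return [_skip_row("multivariate_null", sy.label(), sx.label(), n_obs,
                              "gaussian_lm_multi", 0.0,
                              "more than half of replicates degenerate")]
        summary = summarize_pvalues(p, tuple(alphas), n_failed=n_failed)
        return _rows("multivariate_null", sy.label(), sx.label(), n_obs,
                     "gaussian_lm_multi", 0.0, summary)

    rows: list[dict] = []
    for chunk in _map_cells(one, cells, n_jobs):
        rows.extend(chunk)
    return _finish(rows)


_FAMILY_NULL_MODELS = (
    "gaussian_lm", "quasipoisson_glm", "poisson_olre_glmm", "poisson_glm",
)


def run_family_grid(
    mode: str = "misspecification",
    dist_y: Optional[Sequence] = None,
    dist_x: Optional[Sequence] = None,
    models: Sequence[str] = _FAMILY_NULL_MODELS,
    n_obs: int = 100,
    replicates: int = 50_000,
    base_seed: int = 0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    target_r: float = 0.2,
    calib_n: int = 200_000,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Error-structure comparison grid.

    ``mode="misspecification"``: null data from the five discrete Y
    distributions (default D1, D2, D6, D7, D8) × ten X distributions, fitted
    with each requested model; per-cell rows plus one pooled row per
    (Y, model) panel whose type-I error rate aggregates the ten X
    distributions.

    ``mode="power_comparison"``: a correlation ``target_r`` is induced
    between raw-scale Y (Poisson mean 1, or Bernoulli 0.75) and X (Gaussian,
    gamma, or binomial); each dataset is fitted with a Gaussian error
    structure and with the structure matching Y. Y stays on its raw scale
    (counts/successes), X is standardized per replicate; reported are power,
    slope/intercept bias and precision, and the back-transformed effect
    (inverse link of intercept + slope).
    """
    if mode == "misspecification":
        return _family_null(dist_y, dist_x, models, n_obs, replicates,
                            base_seed, alphas, n_jobs)
    if mode == "power_comparison":
        return _family_power(dist_y, dist_x, n_obs, replicates, base_seed,
                             alphas, target_r, calib_n, n_jobs)
    raise ValueError("mode must be 'misspecification' or 'power_comparison'")


def _family_null(dist_y, dist_x, models, n_obs, replicates, base_seed, alphas,
                 n_jobs) -> pd.DataFrame:
    ys = [_resolve_spec(d) for d in (dist_y or ("D1", "D2", "D6", "D7", "D8"))]
    xs = [_resolve_spec(d) for d in (dist_x or PRESET_IDS)]
    for m in models:
        if m not in _FAMILY_NULL_MODELS:
            raise ValueError(f"unknown model_spec {m!r}")
    cells = [(sy, sx, m) for sy in ys for m in models for sx in xs]

    def one(cell):
        sy, sx, m = cell
        rng = cell_rng(base_seed, "family_null", sy.label(), sx.label(), n_obs, m)
        try:
            p, n_failed = _null_cell_pvalues(sy, sx, n_obs, replicates, rng, m)
        except ValueError as exc:  # e.g. unsupported response for the family
            return sy, m, None, [_skip_row("family_null", sy.label(), sx.label(),
                                           n_obs, m, 0.0, str(exc))]
        if p.size < replicates / 2:
            return sy, m, None, [_skip_row("family_null", sy.label(), sx.label(),
                                           n_obs, m, 0.0, "degenerate cell")]
        summary = summarize_pvalues(p, tuple(alphas), n_failed=n_failed)
        return sy, m, (p, n_failed), _rows("family_null", sy.label(), sx.label(),
                                           n_obs, m, 0.0, summary)

    rows: list[dict] = []
    pooled: dict[tuple[str, str], list] = {}
    for sy, m, payload, cell_rows in _map_cells(one, cells, n_jobs):
        rows.extend(cell_rows)
        if payload is not None:
            pooled.setdefault((sy.label(), m), []).append(payload)
    for (ylab, m), payloads in pooled.items():
        p = np.concatenate([pl[0] for pl in payloads])
        n_failed = sum(pl[1] for pl in payloads)
        summary = summarize_pvalues(p, tuple(alphas), n_failed=n_failed)
        rows.extend(_rows("family_null_pooled", ylab, "pooled", n_obs, m, 0.0,
                          summary))
    return _finish(rows)


_TABLE_MODE_Y = (
    DistributionSpec("poisson", id="poisson_mean1", poisson_mean=1.0),
    DistributionSpec("binomial", id="binomial_mean075", binom_p=0.75),
)
_TABLE_MODE_X = (
    preset("D0"),
    DistributionSpec("gamma", id="gamma_1_10", shape_gamma=1.0, scale_gamma=10.0),
    DistributionSpec("binomial", id="binomial_05", binom_p=0.5),
)


def _family_power(dist_y, dist_x, n_obs, replicates, base_seed, alphas,
                  target_r, calib_n, n_jobs) -> pd.DataFrame:
    ys = [_resolve_spec(d) for d in dist_y] if dist_y else list(_TABLE_MODE_Y)
    xs = [_resolve_spec(d) for d in dist_x] if dist_x else list(_TABLE_MODE_X)
    cells = [(sy, sx) for sy in ys for sx in xs]

    def one(cell):
        sy, sx = cell
        rng = cell_rng(base_seed, "family_power", sy.label(), sx.label(),
                       n_obs, target_r)
        calib = calibrate_intermediate_correlation(
            sy, sx, target_r, n=n_obs, calib_n=calib_n,
            seed=int(rng.integers(2**31)),
        )
        if not calib.converged:
            return [_skip_row("family_power", sy.label(), sx.label(), n_obs,
                              "all", target_r, "effect not attainable")]
        matched_fit = "poisson_glm" if sy.family == "poisson" else "binomial_glm"
        acc: dict[str, dict[str, list]] = {
            "gaussian_glm": {"p": [], "a": [], "b": []},
            matched_fit: {"p": [], "a": [], "b": []},
        }
        failed = {"gaussian_glm": 0, matched_fit: 0}
        for block in _blocks(replicates, n_obs):
            Y, X = sample_correlated_matrix(calib, n_obs, block, rng)
            sd = X.std(axis=1, ddof=1, keepdims=True)
            okx = (sd > 0).ravel()
            Xs = np.where(okx[:, None], (X - X.mean(axis=1, keepdims=True))
                          / np.where(sd > 0, sd, 1.0), X)
            res = batch_gaussian_slope_test(Y, Xs)
            ok = res["valid"] & okx
            acc["gaussian_glm"]["p"].append(res["p"][ok])
            acc["gaussian_glm"]["a"].append(res["intercept"][ok])
            acc["gaussian_glm"]["b"].append(res["slope"][ok])
            failed["gaussian_glm"] += int(block - ok.sum())
            if matched_fit == "poisson_glm":
                resm = batch_poisson_slope_test(Y, Xs)
                pm = resm["p_lrt"]
            else:
                resm = batch_binomial_slope_test(Y, Xs)
                pm = resm["p_lrt"]
            okm = resm["valid"] & okx
            acc[matched_fit]["p"].append(pm[okm])
            acc[matched_fit]["a"].append(resm["a"][okm])
            acc[matched_fit]["b"].append(resm["b"][okm])
            failed[matched_fit] += int(block - okm.sum())
        inv_link = {
            "gaussian_glm": lambda eta: eta,
            "poisson_glm": np.exp,
            "binomial_glm": lambda eta: 1.0 / (1.0 + np.exp(-eta)),
        }
        out = []
        for fit_name, parts in acc.items():
            p = np.concatenate(parts["p"])
            if p.size < replicates / 2:
                out.append(_skip_row("family_power", sy.label(), sx.label(),
                                     n_obs, fit_name, target_r, "degenerate cell"))
                continue
            a = np.concatenate(parts["a"])
            b = np.concatenate(parts["b"])
            effect = inv_link[fit_name](a + b)
            summary = summarize_pvalues(p, tuple(alphas), slopes=b,
                                        n_failed=failed[fit_name])
            out.extend(_rows(
                "family_power", sy.label(), sx.label(), n_obs, fit_name,
                target_r, summary,
                extra={
                    "slope_var": float(b.var(ddof=1)),
                    "intercept_mean": float(a.mean()),
                    "intercept_var": float(a.var(ddof=1)),
                    "intercept_cv": float(a.std(ddof=1) / a.mean())
                    if a.mean() != 0 else np.nan,
                    "effect_mean": float(effect.mean()),
                    "effect_var": float(effect.var(ddof=1)),
                },
            ))
        return out

    rows: list[dict] = []
    for chunk in _map_cells(one, cells, n_jobs):
        rows.extend(chunk)
    return _finish(rows)


# ---------------------------------------------------------------------------
# config and output
# ---------------------------------------------------------------------------


def load_config(path: Union[str, Path]) -> dict:
    """Read a YAML or JSON run configuration; returns a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError("configuration file must hold a mapping")
    return loaded


def write_grid(
    table: pd.DataFrame,
    out: Union[str, Path],
    manifest: Optional[dict] = None,
) -> None:
    """Write the tidy CSV plus a JSON run-manifest next to it.

    The manifest records the exact configuration, seeds and package version,
    and contains nothing volatile, so rerunning the same configuration
    produces byte-identical files.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    payload = dict(manifest or {})
    payload["package_version"] = _pkg_version
    out.with_suffix(out.suffix + ".manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    )
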