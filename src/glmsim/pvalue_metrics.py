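"""Metrics over replicate p-values and slope estimates, plus closed-form
utilities (exact binomial interval, required effect size for a target power).

Under a true null, p-values are Uniform(0,1). Departures are summarized by
the rejection rate at a significance level α, the scale-shift parameter
υ = σ_observed/σ_expected of −log₁₀(p), the fold-bias of the observed
−log₁₀(p) at an expected exponent (3 → the 10⁻³ tail, 4 → the 10⁻⁴ tail),
and pointwise beta-distribution concentration bands for ordered p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PValueSample",
    "MetricsSummary",
    "type_one_error_rate",
    "power_rate",
    "concentration_bands",
    "scale_shift",
    "logp_bias",
    "estimator_summary",
    "EstimatorSummary",
    "clopper_pearson_interval",
    "power_of_effect",
    "required_effect_for_power",
    "summarize_pvalues",
]


@dataclass(frozen=True)
class PValueSample:
    """Replicate p-values for one scenario cell, with labels."""

    p_values: np.ndarray
    n_obs: int
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        if p.size and (not np.all(np.isfinite(p)) or p.min() <= 0 or p.max() > 1):
            raise ValueError("p-values must be finite and lie in (0, 1]")
        object.__setattr__(self, "p_values", p)


ArrayLike = Union[np.ndarray, PValueSample]


def _pvals(sample: ArrayLike) -> np.ndarray:
    if isinstance(sample, PValueSample):
        return sample.p_values
    return np.asarray(sample, dtype=float)


def type_one_error_rate(sample: ArrayLike, alpha: float) -> tuple[float, float]:
    """Fraction of replicates with p ≤ α, with its binomial MC standard
    error √(rate(1−rate)/m)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = _pvals(sample)
    if p.size == 0:
        raise ValueError("empty p-value sample")
    rate = float(np.mean(p <= alpha))
    mc_se = math.sqrt(rate * (1.0 - rate) / p.size)
    return rate, mc_se


#: same estimator applied to non-null scenarios
power_rate = type_one_error_rate


def concentration_bands(m: int, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (lower, upper) bounds for the m ordered p-values of an
    i.i.d. uniform sample: the i-th smallest is Beta(i, m+1−i); the bounds
    are that beta's central quantiles at the given level."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    i = np.arange(1, m + 1)
    a, b = i, m + 1 - i
    tail = (1.0 - level) / 2.0
    return stats.beta.ppf(tail, a, b), stats.beta.ppf(1.0 - tail, a, b)


def expected_neglog10(m: int) -> np.ndarray:
    """−log₁₀ of the uniform plotting positions i/(m+1) (beta means)."""
    return -np.log10(np.arange(1, m + 1) / (m + 1.0))


def scale_shift(sample: ArrayLike) -> float:
    """Scale-shift parameter υ = SD(−log₁₀ p_observed)/SD(−log₁₀ p_expected),
    with expected values at the plotting positions i/(m+1). υ = 1 when the
    p-value distribution matches the uniform null across its whole range."""
    p = _pvals(sample)
    if p.size < 100:
        raise ValueError("need at least 100 replicates for a stable estimate")
    obs = -np.log10(p)
    if obs.std(ddof=1) == 0:
        raise ValueError("degenerate sample: all p-values equal")
    exp = expected_neglog10(p.size)
    return float(obs.std(ddof=1) / exp.std(ddof=1))


def logp_bias(sample: ArrayLike, exponent: float) -> float:
    """Fold-bias of observed vs expected −log₁₀(p) at tail probability
    10^−exponent: −log₁₀ of the empirical 10^−exponent quantile of p,
    divided by the exponent. 1 means the tail is calibrated; 3.36 at
    exponent 3 means p-values near 10⁻¹⁰ occur at rate 10⁻³."""
    p = _pvals(sample)
    required = int(10 ** exponent * 10)
    if p.size < required:
        raise ValueError(
            f"need at least {required} replicates to estimate the "
            f"10^-{exponent:g} quantile"
        )
    q = float(np.quantile(p, 10.0 ** (-exponent)))
    return -math.log10(q) / exponent


@dataclass(frozen=True)
class EstimatorSummary:
    mean: float
    cv: float
    sd: float
    n: int
    negative_mean: bool
    unstable_cv: bool


def estimator_summary(slopes: np.ndarray, true_b: Optional[float] = None) -> EstimatorSummary:
    """Mean (bias) and coefficient of variation SD/mean (precision) of
    replicate slope estimates. A mean near zero makes the CV unstable; the
    value is still returned but flagged."""
    b = np.asarray(slopes, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 estimates")
    mean = float(b.mean())
    sd = float(b.std(ddof=1))
    # CV is meaningless when the mean is not distinguishable from zero
    unstable = abs(mean) < 3.0 * sd / math.sqrt(b.size)
    cv = sd / mean if mean != 0 else math.inf
    return EstimatorSummary(mean, float(cv), sd, b.size, mean < 0, unstable)


def clopper_pearson_interval(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval from beta
    quantiles; the lower bound is 0 at 0 successes and the upper is 1 at
    ``trials`` successes."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(tail, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - tail, successes + 1, trials - successes)
    )
    return lower, upper


def power_of_effect(n: int, r: float, alpha: float = 0.05) -> float:
    """Power of the two-sided t test of a standardized slope (equivalently a
    Pearson correlation) at effect r: df = n−2, noncentrality
    δ = r√n/√(1−r²)."""
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    delta = r * math.sqrt(n) / math.sqrt(1.0 - r * r)
    upper = stats.nct.sf(t_crit, df, delta)
    lower = stats.nct.cdf(-t_crit, df, delta)
    # the far tail underflows to nan at large |delta|; it is numerically 0 there
    if math.isnan(upper):
        upper = 1.0 if delta > t_crit else 0.0
    if math.isnan(lower):
        lower = 1.0 if delta < -t_crit else 0.0
    return float(min(max(upper + lower, 0.0), 1.0))


def required_effect_for_power(
    n: int,
    target_power: float = 0.5,
    alpha: float = 0.05,
    round_digits: Optional[int] = None,
) -> float:
    """Smallest correlation r whose two-sided slope t test attains the target
    power, by bisection of the noncentral-t power function to 1e−6."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0.0 < target_power < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("target_power and alpha must lie in (0, 1)")
    hi = 1.0 - 1e-9
    if power_of_effect(n, hi, alpha) < target_power:
        raise ValueError("target power unreachable at this n and alpha")
    r = float(
        optimize.brentq(
            lambda x: power_of_effect(n, x, alpha) - target_power,
            1e-12,
            hi,
            xtol=1e-6,
        )
    )
    return round(r, round_digits) if round_digits is not None else r


@dataclass(frozen=True)
class MetricsSummary:
    """Per-cell metrics: α-indexed rejection rates with MC standard errors,
    scale shift υ, fold-bias of −log₁₀ p, slope bias/precision, accounting."""

    rates: dict[float, tuple[float, float]]
    scale_shift_upsilon: Optional[float]
    logp_bias: dict[float, float]
    slope_mean: Optional[float]
    slope_cv: Optional[float]
    n_replicates: int
    n_failed: int


def summarize_pvalues(
    p_values: np.ndarray,
    alphas: tuple[float, ...] = (0.05, 0.001, 0.0001),
    slopes: Optional[np.ndarray] = None,
    logp_exponents: tuple[float, ...] = (3.0, 4.0),
    n_failed: int = 0,
) -> MetricsSummary:
    """Bundle the cell metrics that the replicate count supports: rejection
    rates always; υ from 100 replicates; each fold-bias exponent only when
    the corresponding tail quantile is estimable."""
    p = np.asarray(p_values, dtype=float)
    rates = {a: type_one_error_rate(p, a) for a in alphas}
    upsilon = scale_shift(p) if p.size >= 100 and np.unique(p).size > 1 else None
    biases: dict[float, float] = {}
    for expo in logp_exponents:
        if p.size >= 10 ** expo * 10:
            biases[expo] = logp_bias(p, expo)
    slope_mean = slope_cv = None
    if slopes is not None and len(slopes) >= 2:
        summ = estimator_summary(slopes)
        slope_mean, slope_cv = summ.mean, summ.cv
    return MetricsSummary(
        rates=rates,
        scale_shift_upsilon=upsilon,
        logp_bias=biases,
        slope_mean=slope_mean,
        slope_cv=slope_cv,
        n_replicates=int(p.size),
        n_failed=int(n_failed),
    )
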