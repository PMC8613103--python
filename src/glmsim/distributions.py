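"""Benchmark marginal distributions (D0–D9) and moment utilities.

The simulation study rests on ten marginal distributions — five continuous
and five discrete — chosen to violate normality severely: heavy skew
(gamma with shape 0.1), heavy tails (Student's t with 4 df), zero-inflation,
categorization, and Bernoulli extremes. ``PRESETS`` holds the canonical
parameterizations; arbitrary :class:`DistributionSpec` instances cover user
variations of the same families.

Post-processing order for the composite families is: base draw →
categorization into equal-probability bins of the base distribution →
zero-inflation (zeros replace values with probability ``zero_level``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional

import numpy as np
from scipy import stats

__all__ = [
    "ConfigurationError",
    "DistributionSpec",
    "MomentSet",
    "OutlierTendency",
    "PRESETS",
    "preset",
    "analytic_moments",
    "empirical_moments",
    "outlier_tendency",
    "rin_transform",
    "sample_distribution",
    "sample_matrix",
    "spec_from_config",
]


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent distribution parameters."""


#: parameters each family requires (all others must be absent)
FAMILY_PARAMS: dict[str, frozenset[str]] = {
    "gaussian": frozenset({"mean_gauss", "sd_gauss"}),
    "binomial": frozenset({"binom_p"}),
    "gaussian_zero_categorical": frozenset(
        {"mean_gauss", "sd_gauss", "n_categories", "zero_level"}
    ),
    "gaussian_zero": frozenset({"mean_gauss", "sd_gauss", "zero_level"}),
    "absolute_gaussian": frozenset({"mean_gauss", "sd_gauss"}),
    "students_t": frozenset({"df_student"}),
    "gamma_categorical": frozenset({"shape_gamma", "scale_gamma", "n_categories"}),
    "negative_binomial_gamma_poisson": frozenset({"shape_gamma", "scale_gamma"}),
    "gamma": frozenset({"shape_gamma", "scale_gamma"}),
    "poisson": frozenset({"poisson_mean"}),
}

#: families whose support is a finite/countable set of non-negative values
DISCRETE_FAMILIES = frozenset(
    {
        "binomial",
        "gaussian_zero_categorical",
        "gamma_categorical",
        "negative_binomial_gamma_poisson",
        "poisson",
    }
)


@dataclass(frozen=True)
class DistributionSpec:
    """Parameterized recipe for one marginal distribution.

    Exactly the parameters required by ``family`` may be set; supplying an
    extraneous parameter (or omitting a required one) raises
    :class:`ConfigurationError` naming the offending field.
    """

    family: str
    id: Optional[str] = None
    mean_gauss: Optional[float] = None
    sd_gauss: Optional[float] = None
    zero_level: Optional[float] = None
    n_categories: Optional[int] = None
    shape_gamma: Optional[float] = None
    scale_gamma: Optional[float] = None
    df_student: Optional[float] = None
    binom_p: Optional[float] = None
    poisson_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_PARAMS:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of "
                f"{sorted(FAMILY_PARAMS)}"
            )
        required = FAMILY_PARAMS[self.family]
        param_fields = {
            f.name for f in fields(self) if f.name not in ("family", "id")
        }
        for name in sorted(required):
            if getattr(self, name) is None:
                raise ConfigurationError(
                    f"family {self.family!r} requires parameter {name!r}"
                )
        for name in sorted(param_fields - required):
            if getattr(self, name) is not None:
                raise ConfigurationError(
                    f"parameter {name!r} is not used by family {self.family!r}"
                )
        # range checks
        if self.sd_gauss is not None and self.sd_gauss <= 0:
            raise ConfigurationError("sd_gauss must be positive")
        for name in ("zero_level", "binom_p"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("shape_gamma", "scale_gamma", "df_student", "poisson_mean"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_categories is not None and self.n_categories < 1:
            raise ConfigurationError("n_categories must be a positive integer")

    @property
    def discrete(self) -> bool:
        return self.family in DISCRETE_FAMILIES

    def label(self) -> str:
        return self.id if self.id is not None else self.family


PRESETS: dict[str, DistributionSpec] = {
    "D0": DistributionSpec("gaussian", id="D0", mean_gauss=0.0, sd_gauss=1.0),
    "D1": DistributionSpec("binomial", id="D1", binom_p=0.5),
    "D2": DistributionSpec(
        "gaussian_zero_categorical",
        id="D2",
        mean_gauss=3.0,
        sd_gauss=1.0,
        n_categories=5,
        zero_level=0.5,
    ),
    "D3": DistributionSpec(
        "gaussian_zero", id="D3", mean_gauss=3.0, sd_gauss=1.0, zero_level=0.5
    ),
    "D4": DistributionSpec("absolute_gaussian", id="D4", mean_gauss=0.0, sd_gauss=1.0),
    "D5": DistributionSpec("students_t", id="D5", df_student=4.0),
    "D6": DistributionSpec(
        "gamma_categorical", id="D6", shape_gamma=1.0, scale_gamma=10.0, n_categories=3
    ),
    "D7": DistributionSpec(
        "negative_binomial_gamma_poisson", id="D7", shape_gamma=1.0, scale_gamma=10.0
    ),
    "D8": DistributionSpec("binomial", id="D8", binom_p=0.9),
    "D9": DistributionSpec("gamma", id="D9", shape_gamma=0.1, scale_gamma=100.0),
}

PRESET_IDS = tuple(PRESETS)


def preset(name: str) -> DistributionSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; expected one of {list(PRESETS)}"
        ) from None


def _categorize(values: np.ndarray, n_categories: int, base) -> np.ndarray:
    """Map draws onto 1..n_categories via equal-probability bins of ``base``.

    The bin edges are the base distribution's quantiles at i/n_categories, so
    each category carries probability 1/n_categories exactly.
    """
    edges = base.ppf(np.arange(1, n_categories) / n_categories)
    return (np.digitize(values, edges) + 1).astype(float)


def sample_matrix(
    spec: DistributionSpec, shape, rng: np.random.Generator
) -> np.ndarray:
    """Draw an array of i.i.d. values from ``spec`` using ``rng``.

    This is the engine behind :func:`sample_distribution`; grid runners call
    it directly with (replicates, n) shapes.
    """
    fam = spec.family
    if fam == "gaussian":
        return rng.normal(spec.mean_gauss, spec.sd_gauss, shape)
    if fam == "binomial":
        return rng.binomial(1, spec.binom_p, shape).astype(float)
    if fam == "students_t":
        return rng.standard_t(spec.df_student, shape)
    if fam == "absolute_gaussian":
        return np.abs(rng.normal(spec.mean_gauss, spec.sd_gauss, shape))
    if fam == "gamma":
        return rng.gamma(spec.shape_gamma, spec.scale_gamma, shape)
    if fam == "poisson":
        return rng.poisson(spec.poisson_mean, shape).astype(float)
    if fam == "negative_binomial_gamma_poisson":
        lam = rng.gamma(spec.shape_gamma, spec.scale_gamma, shape)
        return rng.poisson(lam).astype(float)
    if fam == "gaussian_zero":
        v = rng.normal(spec.mean_gauss, spec.sd_gauss, shape)
        v[rng.random(shape) < spec.zero_level] = 0.0
        return v
    if fam == "gaussian_zero_categorical":
        base = stats.norm(spec.mean_gauss, spec.sd_gauss)
        v = _categorize(
            rng.normal(spec.mean_gauss, spec.sd_gauss, shape), spec.n_categories, base
        )
        v[rng.random(shape) < spec.zero_level] = 0.0
        return v
    if fam == "gamma_categorical":
        base = stats.gamma(spec.shape_gamma, scale=spec.scale_gamma)
        return _categorize(
            rng.gamma(spec.shape_gamma, spec.scale_gamma, shape),
            spec.n_categories,
            base,
        )
    raise ConfigurationError(f"unhandled family {fam!r}")  # pragma: no cover


def sample_distribution(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. values; bit-reproducible for fixed (spec, n, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sample_matrix(spec, n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentSet:
    """First four moments; kurtosis is non-excess (Gaussian = 3).

    ``skewness``/``kurtosis`` may be ``math.inf`` (heavy-tailed t) or ``None``
    when undefined (zero variance, or the moment does not exist); ``note``
    says why. ``source`` records whether values are closed-form or estimated.
    """

    mean: float
    variance: float
    skewness: Optional[float]
    kurtosis: Optional[float]
    source: str = "analytic"
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.skewness is not None and self.kurtosis is not None


def empirical_moments(values: np.ndarray) -> MomentSet:
    """Sample moments with the plain moment estimators (no bias correction):
    skewness m3/m2^{3/2}, kurtosis m4/m2² with mi the central sample moments.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    mean = float(x.mean())
    d = x - mean
    m2 = float((d**2).mean())
    if m2 == 0.0:
        return MomentSet(mean, 0.0, None, None, source="empirical",
                         note="zero variance: skewness/kurtosis undefined")
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return MomentSet(mean, m2, m3 / m2**1.5, m4 / m2**2, source="empirical")


def _halfnormal_moments(sd: float) -> MomentSet:
    mean = sd * math.sqrt(2.0 / math.pi)
    var = sd**2 * (1.0 - 2.0 / math.pi)
    skew = math.sqrt(2.0) * (4.0 - math.pi) / (math.pi - 2.0) ** 1.5
    kurt = 3.0 + 8.0 * (math.pi - 3.0) / (math.pi - 2.0) ** 2
    return MomentSet(mean, var, skew, kurt)


def analytic_moments(
    spec: DistributionSpec,
    fallback_n: int = 2_000_000,
    fallback_seed: int = 1_000_003,
) -> MomentSet:
    """Closed-form moments of the post-processed distribution where they
    exist; otherwise an empirical estimate on ``fallback_n`` draws, flagged
    via ``source="empirical"``.

    Closed forms cover: gaussian, binomial (Bernoulli), gamma, the
    gamma–Poisson mixture, Student's t (infinite kurtosis flagged for
    df ≤ 4), the half-normal (absolute Gaussian centred at 0), and Poisson.
    """
    fam = spec.family
    if fam == "gaussian":
        return MomentSet(spec.mean_gauss, spec.sd_gauss**2, 0.0, 3.0)
    if fam == "binomial":
        p = spec.binom_p
        q = 1.0 - p
        if p in (0.0, 1.0):
            return MomentSet(p, 0.0, None, None,
                             note="degenerate Bernoulli: zero variance")
        return MomentSet(
            p, p * q, (1 - 2 * p) / math.sqrt(p * q), 3.0 + (1 - 6 * p * q) / (p * q)
        )
    if fam == "gamma":
        k, th = spec.shape_gamma, spec.scale_gamma
        return MomentSet(k * th, k * th**2, 2.0 / math.sqrt(k), 3.0 + 6.0 / k)
    if fam == "negative_binomial_gamma_poisson":
        # gamma-Poisson mixture == negative binomial with r=shape, p=1/(1+scale)
        k, th = spec.shape_gamma, spec.scale_gamma
        r, p = k, 1.0 / (1.0 + th)
        q = 1.0 - p
        mean = k * th
        var = k * th * (1.0 + th)
        skew = (2.0 - p) / math.sqrt(r * q)
        kurt = 3.0 + 6.0 / r + p**2 / (r * q)
        return MomentSet(mean, var, skew, kurt)
    if fam == "students_t":
        df = spec.df_student
        if df <= 2:
            return MomentSet(0.0, math.inf, None, None,
                             note=f"t with df={df}: variance infinite")
        var = df / (df - 2.0)
        skew = 0.0 if df > 3 else None
        if df > 4:
            kurt: Optional[float] = 3.0 + 6.0 / (df - 4.0)
            note = ""
        else:
            kurt = math.inf
            note = f"t with df={df} <= 4: kurtosis infinite"
        return MomentSet(0.0, var, skew, kurt, note=note)
    if fam == "absolute_gaussian" and spec.mean_gauss == 0.0:
        return _halfnormal_moments(spec.sd_gauss)
    if fam == "poisson":
        mu = spec.poisson_mean
        return MomentSet(mu, mu, 1.0 / math.sqrt(mu), 3.0 + 1.0 / mu)
    # categorized / zero-inflated / folded families: estimate and flag
    draws = sample_matrix(spec, fallback_n, np.random.default_rng(fallback_seed))
    est = empirical_moments(draws)
    return replace(est, note=f"no closed form for family {fam!r}; "
                             f"estimated from {fallback_n} draws")


# ---------------------------------------------------------------------------
# rank-based inverse normal transformation
# ---------------------------------------------------------------------------


def rin_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (rankit) scores Φ⁻¹((rank − 0.5)/n).

    Ties receive average ranks. Monotone in the input; output is
    approximately standard normal for any continuous input shape.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(x == x.flat[0]):
        raise ValueError("all values tied: rankit scores undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size).reshape(x.shape)


# ---------------------------------------------------------------------------
# outlier tendency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierTendency:
    """Average fraction of high-influence points (Cook's D above 4/(n−k−1))
    when a standard-normal response is regressed on draws from the spec."""

    proportion: float
    n_replicates: int
    n_dropped: int

    @property
    def all_dropped(self) -> bool:
        return self.n_replicates == 0


def outlier_tendency(
    spec: DistributionSpec,
    n: int = 10,
    reps: int = 5000,
    seed: int = 0,
) -> OutlierTendency:
    """Score a distribution's tendency to produce influential observations.

    For each replicate, a Gaussian response (D0) is regressed on ``n`` draws
    from ``spec`` and the fraction of points with Cook's distance above
    4/(n−2) is recorded; the score is the average fraction over replicates.
    Replicates with degenerate predictors (zero variance) or an exact-fit
    response are dropped and counted.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    X = sample_matrix(spec, (reps, n), rng)
    Y = rng.standard_normal((reps, n))
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc**2).sum(axis=1)
    ok = sxx > 0
    X, Y, Xc, sxx = X[ok], Y[ok], Xc[ok], sxx[ok]
    if X.shape[0] == 0:
        return OutlierTendency(math.nan, 0, reps)
    b = (Xc * Y).sum(axis=1) / sxx
    a = Y.mean(axis=1) - b * X.mean(axis=1)
    e = Y - a[:, None] - b[:, None] * X
    rss = (e**2).sum(axis=1)
    ok2 = rss > 0
    n_dropped = int(reps - ok2.sum())
    X, Xc, sxx, e, rss = X[ok2], Xc[ok2], sxx[ok2], e[ok2], rss[ok2]
    if X.shape[0] == 0:
        return OutlierTendency(math.nan, 0, reps)
    s2 = rss / (n - 2)
    h = 1.0 / n + Xc**2 / sxx[:, None]
    # perfect-leverage points (h -> 1) have a zero residual and an undefined
    # Cook's D; they are scored 0 here (the screening thresholds of the
    # diagnostics module are a separate concern)
    one_minus_h = np.clip(1.0 - h, 1e-12, None)
    with np.errstate(over="ignore"):
        d = (e**2 / (s2[:, None] * one_minus_h)) * h / (2.0 * one_minus_h)
    d = np.where(h >= 1.0 - 1e-10, 0.0, d)
    frac = (d > 4.0 / (n - 2)).mean(axis=1)
    return OutlierTendency(float(frac.mean()), int(X.shape[0]), n_dropped)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_CONFIG_FAMILY_NAMES = {
    "gaussian": "gaussian",
    "binomial": "binomial",
    "gaussianzerocategorical": "gaussian_zero_categorical",
    "gaussian_zero_categorical": "gaussian_zero_categorical",
    "gaussianzero": "gaussian_zero",
    "gaussian_zero": "gaussian_zero",
    "absolutegaussian": "absolute_gaussian",
    "absolute_gaussian": "absolute_gaussian",
    "studentst": "students_t",
    "students_t": "students_t",
    "gammacategorical": "gamma_categorical",
    "gamma_categorical": "gamma_categorical",
    "negativebinomial": "negative_binomial_gamma_poisson",
    "negative_binomial_gamma_poisson": "negative_binomial_gamma_poisson",
    "gamma": "gamma",
    "poisson": "poisson",
}

# dotted config keys (role-suffixed, e.g. "ShapeY.gamma") -> spec field
_DOTTED_KEYS = {
    "mean{role}.gauss": "mean_gauss",
    "sd{role}.gauss": "sd_gauss",
    "zerolevel{role}.zero": "zero_level",  # for binomial: success probability
    "ncategories{role}.cat": "n_categories",
    "shape{role}.gamma": "shape_gamma",
    "scale{role}.gamma": "scale_gamma",
    "df{role}.student": "df_student",
    "mean{role}.poisson": "poisson_mean",
}

_SNAKE_KEYS = {
    "mean_gauss", "sd_gauss", "zero_level", "n_categories",
    "shape_gamma", "scale_gamma", "df_student", "binom_p", "poisson_mean",
}


def spec_from_config(config: Mapping[str, object], role: str = "Y") -> DistributionSpec:
    """Build a :class:`DistributionSpec` from a config mapping.

    Two naming conventions are accepted and may not be mixed with unknown
    keys: the role-suffixed dotted names used in the benchmark's distribution
    table (``DistributionY="Gamma", ShapeY.gamma=0.1, ScaleY.gamma=100``) and
    plain snake_case (``family="gamma", shape_gamma=0.1, scale_gamma=100``).
    A bare preset id string ("D0".."D9") is also accepted via ``{"preset": id}``.
    Unknown keys raise :class:`ConfigurationError`.
    """
    role_l = role.lower()
    items = {str(k): v for k, v in config.items()}
    if set(items) == {"preset"}:
        return preset(str(items["preset"]))
    lowered = {k.lower(): (k, v) for k, v in items.items()}
    fam_key = None
    for cand in (f"distribution{role_l}", "family"):
        if cand in lowered:
            fam_key = cand
            break
    if fam_key is None:
        raise ConfigurationError(
            f"config must name a family via 'Distribution{role}' or 'family'"
        )
    raw_family = str(lowered[fam_key][1]).lower()
    if raw_family not in _CONFIG_FAMILY_NAMES:
        raise ConfigurationError(f"unknown distribution name {lowered[fam_key][1]!r}")
    family = _CONFIG_FAMILY_NAMES[raw_family]

    kwargs: dict[str, object] = {}
    dotted = {
        pat.format(role=role_l): field_name for pat, field_name in _DOTTED_KEYS.items()
    }
    for key_l, (orig, value) in lowered.items():
        if key_l in (fam_key, "id"):
            continue
        if key_l in dotted:
            target = dotted[key_l]
            if family == "binomial" and target == "zero_level":
                target = "binom_p"  # table convention: zeroLevel is the success prob
            kwargs[target] = value
        elif key_l in _SNAKE_KEYS:
            kwargs[key_l] = value
        else:
            raise ConfigurationError(f"unknown configuration key {orig!r}")
    if "n_categories" in kwargs:
        kwargs["n_categories"] = int(kwargs["n_categories"])  # type: ignore[arg-type]
    for k in list(kwargs):
        if k != "n_categories":
            kwargs[k] = float(kwargs[k])  # type: ignore[arg-type]
    ident = items.get("id")
    return DistributionSpec(family, id=None if ident is None else str(ident), **kwargs)  # type: ignore[arg-type]
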