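"""Influence, leverage and discrepancy diagnostics for least-squares fits.

Implements the classical trio for a fit with k slopes and n observations:
studentized residuals R (discrepancy), hat values H (leverage) and Cook's
distances D (influence), with the screening thresholds |R| > 2,
H > 2(k+1)/n and D > 4/(n−k−1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_fitting import FitResult

__all__ = ["DiagnosticSet", "leverage_and_influence"]


@dataclass(frozen=True)
class DiagnosticSet:
    studentized_residuals: np.ndarray
    hat_values: np.ndarray
    cooks_distances: np.ndarray
    prop_R_exceed: float
    prop_H_exceed: float
    prop_D_exceed: float
    k: int
    n: int


def leverage_and_influence(fit: FitResult, external: bool = False) -> DiagnosticSet:
    """Diagnostics from a Gaussian linear fit.

    Residuals are internally studentized, rᵢ = eᵢ/(σ̂√(1−hᵢ)) with σ̂² the
    unbiased error-variance estimate (set ``external`` for the leave-one-out
    variant). Cook's distance uses the algebraic identity
    Dᵢ = rᵢ²hᵢ/((k+1)(1−hᵢ)), which equals the leave-one-out definition.
    Perfect-leverage points (hᵢ = 1) have undefined residuals; they are
    returned as ±inf and counted as exceeding every threshold.
    """
    if fit.family != "gaussian" or fit.model_matrix is None:
        raise ValueError("diagnostics require a Gaussian linear fit with its design")
    X = fit.model_matrix
    n, p = X.shape
    k = p - 1
    q, _ = np.linalg.qr(X)
    h = (q**2).sum(axis=1)
    e = fit.residuals_response
    rss = float(e @ e)
    sigma2 = rss / (n - p)
    at_bound = h >= 1.0 - 1e-10
    one_minus_h = np.where(at_bound, np.nan, 1.0 - h)
    if sigma2 > 0:
        r = e / np.sqrt(sigma2 * one_minus_h)
    else:
        r = np.where(np.isnan(one_minus_h), np.nan, 0.0)
    if external:
        # leave-one-out studentization from the internal one
        with np.errstate(invalid="ignore"):
            r = r * np.sqrt((n - p - 1) / np.clip(n - p - r**2, 1e-12, None))
    with np.errstate(invalid="ignore"):
        d = r**2 * h / (p * one_minus_h)
    r = np.where(at_bound, math.inf * np.sign(np.where(e == 0, 1.0, e)), r)
    d = np.where(at_bound, math.inf, d)
    with np.errstate(invalid="ignore"):
        prop_r = float(np.mean(np.abs(r) > 2.0))
        prop_h = float(np.mean(h > 2.0 * p / n))
        prop_d = float(np.mean(d > 4.0 / (n - p)))
    return DiagnosticSet(
        studentized_residuals=r,
        hat_values=h,
        cooks_distances=d,
        prop_R_exceed=prop_r,
        prop_H_exceed=prop_h,
        prop_D_exceed=prop_d,
        k=k,
        n=n,
    )
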