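"""Weibull age distributions on the physiological-age axis.

Survival, cumulative oviposition and pre-oviposition completion are all
expressed as Weibull functions of physiological age Px (dimensionless
accumulated development).  Two families are used:

* two-parameter, ``exp(−(Px/α)^β)`` as a decreasing survival curve or its
  increasing complement as a cumulative oviposition curve (OORM);
* three-parameter, ``1 − exp(−((Px − γ)/η)^β)`` with an onset age γ below
  which the proportion is exactly zero (ORM, PCDM).

Note on the OORM form: the source survival equation is decreasing, but a
cumulative oviposition proportion must increase, and the fitted OORM
scale α = 0.2401 is described as the age of 50% fecundity — only
consistent with the increasing complement, which is what
:func:`weibull2_cdf` implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Weibull2Params",
    "Weibull3Params",
    "survival_prop",
    "weibull2_cdf",
    "weibull3_cdf",
    "weibull2_quantile",
    "weibull3_quantile",
]


def _as_age(px, allow_negative=False):
    arr = np.asarray(px, dtype=float)
    if not allow_negative and np.any(arr < 0):
        raise ValueError("physiological age must be non-negative")
    return arr, arr.ndim == 0


@dataclass(frozen=True)
class Weibull2Params:
    """Scale ``alpha`` (physiological age) and shape ``beta``; both > 0."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"alpha and beta must be positive, got ({self.alpha}, {self.beta})"
            )


@dataclass(frozen=True)
class Weibull3Params:
    """Onset ``gamma`` (≥ 0), scale ``eta`` (> 0) and shape ``beta`` (> 0)."""

    gamma: float
    eta: float
    beta: float

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if self.eta <= 0 or self.beta <= 0:
            raise ValueError(
                f"eta and beta must be positive, got ({self.eta}, {self.beta})"
            )


def survival_prop(params: Weibull2Params, px) -> float | np.ndarray:
    """Proportion of adults alive at physiological age ``px``.

    ``exp(−(px/α)^β)``: equals 1 at px = 0, decreases monotonically, and
    stays strictly positive.  Negative ages raise ``ValueError``.
    """
    arr, scalar = _as_age(px)
    val = np.exp(-np.power(arr / params.alpha, params.beta))
    return float(val) if scalar else val


def weibull2_cdf(params: Weibull2Params, px) -> float | np.ndarray:
    """Cumulative proportion ``1 − exp(−(px/α)^β)`` (increasing complement).

    Used for the oviposition-phase cumulative egg distribution (OORM).
    Identically ``1 − survival_prop`` with the same parameters.
    """
    arr, scalar = _as_age(px)
    val = -np.expm1(-np.power(arr / params.alpha, params.beta))
    return float(val) if scalar else val


def weibull3_cdf(params: Weibull3Params, px) -> float | np.ndarray:
    """Cumulative proportion with onset: 0 for ``px ≤ γ``, else the Weibull CDF.

    Returns exactly 0 (not an error) below the onset age so simulators can
    evaluate it on whole age grids.
    """
    arr, scalar = _as_age(px, allow_negative=True)
    shifted = np.maximum(arr - params.gamma, 0.0)
    val = -np.expm1(-np.power(shifted / params.eta, params.beta))
    return float(val) if scalar else val


def weibull2_quantile(params: Weibull2Params, q) -> float | np.ndarray:
    """Physiological age at which :func:`weibull2_cdf` reaches ``q``."""
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("quantile level must lie in [0, 1)")
    val = params.alpha * np.power(-np.log1p(-arr), 1.0 / params.beta)
    return float(val) if arr.ndim == 0 else val


def weibull3_quantile(params: Weibull3Params, q) -> float | np.ndarray:
    """Physiological age at which :func:`weibull3_cdf` reaches ``q``.

    At the level ``q = 1 − e⁻¹`` this is γ + η, the age the fitted curves
    report as their headline "50%" point.
    """
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("quantile level must lie in [0, 1)")
    val = params.gamma + params.eta * np.power(-np.log1p(-arr), 1.0 / params.beta)
    return float(val) if arr.ndim == 0 else val
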