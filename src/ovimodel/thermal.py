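"""Temperature-response functions for adult *Bactrocera dorsalis* reproduction.

Every function maps a daily mean temperature (°C) to a biological rate
(per day) or to a lifetime egg capacity.  Rates feed the physiological-age
clocks of the oviposition simulators; the fecundity curve caps lifetime
egg production.  All evaluators are NumPy-vectorised: scalars in, scalar
out; arrays in, array out.

Conventions
-----------
* Rates that represent development or counts (``linear_rate``,
  ``fecundity``, ``preovi_rate``) clamp to zero outside their biological
  support — negative eggs or negative development are meaningless
  downstream.
* The oviposition-phase rate ``ovi_rate`` is an empirical four-term curve
  fitted only on 16.7–34.9 °C data and diverges at low temperature via its
  ``d·exp(−T)`` term; it is deliberately *not* clamped here.  Simulators
  gate oviposition-phase progress by the fecundity support instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearRateParams",
    "AgingParams",
    "FecundityParams",
    "Briere2Params",
    "OdrmParams",
    "linear_rate",
    "ldt_tc",
    "aging_rate",
    "fecundity",
    "preovi_rate",
    "ovi_rate",
]


def _as_float(x):
    """Return ``x`` as float64 ndarray plus a flag for scalar input."""
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _maybe_scalar(arr, scalar):
    return float(arr) if scalar else arr


@dataclass(frozen=True)
class LinearRateParams:
    """Slope/intercept of a degree-day regression ``rate = a·T + b``.

    ``slope_a`` is in rate/(day·°C), ``intercept_b`` in rate/day.  The low
    developmental threshold (−b/a) and thermal constant (1/a) are derived
    by :func:`ldt_tc` and require a nonzero slope.
    """

    slope_a: float
    intercept_b: float


@dataclass(frozen=True)
class AgingParams:
    """Adult aging-rate curve ``A(T) = r0 + exp((T − T_H)/c)``.

    ``r0`` is the minimum aging rate per day (reciprocal of the innate
    longevity ceiling), ``T_H`` the temperature (°C) where the rate
    reaches ~1 + r0 (adults survive less than a day), and ``c`` a
    temperature scale (°C).
    """

    r0: float
    T_H: float
    c: float

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")


@dataclass(frozen=True)
class FecundityParams:
    """Quadratic lifetime-fecundity curve ``F(T) = α·(T − T_L)·(T_H − T)``."""

    alpha_f: float
    T_L: float
    T_H: float

    def __post_init__(self):
        if not self.T_L < self.T_H:
            raise ValueError(f"require T_L < T_H, got {self.T_L} >= {self.T_H}")
        if self.alpha_f <= 0:
            raise ValueError(f"alpha_f must be positive, got {self.alpha_f}")


@dataclass(frozen=True)
class Briere2Params:
    """Briere-2 development rate ``D(T) = α·T·(T − T_L)·(T_H − T)^(1/m)``."""

    alpha_p: float
    T_L: float
    T_H: float
    m: float

    def __post_init__(self):
        if not self.T_L < self.T_H:
            raise ValueError(f"require T_L < T_H, got {self.T_L} >= {self.T_H}")
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")


@dataclass(frozen=True)
class OdrmParams:
    """Empirical oviposition-phase rate ``D_o(T) = a + b·e^T + c/T² + d·e^(−T)``.

    Purely empirical; no invariants beyond finite coefficients.
    """

    a: float
    b: float
    c: float
    d: float


def linear_rate(params: LinearRateParams, T) -> float | np.ndarray:
    """Evaluate a degree-day regression, clamped at zero.

    Returns ``max(0, a·T + b)``; a development rate can not be negative.
    """
    T, scalar = _as_float(T)
    rate = np.maximum(0.0, params.slope_a * T + params.intercept_b)
    return _maybe_scalar(rate, scalar)


def ldt_tc(params: LinearRateParams) -> tuple[float, float]:
    """Low developmental threshold (°C) and thermal constant (degree-days).

    LDT = −b/a is the temperature where the regression predicts zero
    rate; TC = 1/a is the degree-day sum needed to complete the process.

    Raises
    ------
    ValueError
        If the slope is zero (threshold undefined).
    """
    if params.slope_a == 0:
        raise ValueError("zero slope: LDT and TC are undefined")
    return -params.intercept_b / params.slope_a, 1.0 / params.slope_a


def aging_rate(params: AgingParams, T) -> float | np.ndarray:
    """Adult aging rate per day, ``r0 + exp((T − T_H)/c)``.

    Strictly positive and strictly increasing in temperature; its
    reciprocal approximates the expected adult longevity in days.
    """
    T, scalar = _as_float(T)
    rate = params.r0 + np.exp((T - params.T_H) / params.c)
    return _maybe_scalar(rate, scalar)


def fecundity(params: FecundityParams, T) -> float | np.ndarray:
    """Lifetime egg capacity per female at temperature ``T``.

    ``α·(T − T_L)·(T_H − T)`` inside the limits, exactly zero at and
    beyond them: no reproduction outside (T_L, T_H).
    """
    T, scalar = _as_float(T)
    val = params.alpha_f * (T - params.T_L) * (params.T_H - T)
    val = np.where((T <= params.T_L) | (T >= params.T_H), 0.0, val)
    return _maybe_scalar(np.maximum(val, 0.0), scalar)


def preovi_rate(params: Briere2Params, T) -> float | np.ndarray:
    """Pre-oviposition development rate per day (Briere-2 curve).

    Zero at and outside [T_L, T_H]; the fractional exponent is applied
    only on the valid branch.
    """
    T, scalar = _as_float(T)
    inside = (T > params.T_L) & (T < params.T_H)
    # Evaluate the power only where its base is positive.
    base = np.where(inside, params.T_H - T, 0.0)
    val = np.where(
        inside,
        params.alpha_p * T * (T - params.T_L) * np.power(base, 1.0 / params.m),
        0.0,
    )
    return _maybe_scalar(np.maximum(val, 0.0), scalar)


def ovi_rate(params: OdrmParams, T) -> float | np.ndarray:
    """Oviposition-phase development rate per day (empirical U-shaped curve).

    Not clamped: the expression is valid as fitted only on the observed
    16.7–34.9 °C range and explodes at low temperature through
    ``d·exp(−T)``.  Callers (the simulators) gate by the fecundity
    support.

    Raises
    ------
    ValueError
        If any temperature is ≤ 0 °C (the ``c/T²`` term is undefined).
    """
    T, scalar = _as_float(T)
    if np.any(T <= 0):
        raise ValueError("ovi_rate is undefined for T <= 0 °C")
    val = (
        params.a
        + params.b * np.exp(T)
        + params.c / (T * T)
        + params.d * np.exp(-T)
    )
    return _maybe_scalar(val, scalar)
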