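"""Daily oviposition simulators over arbitrary temperature series.

Two cohort simulators predict the egg sequence laid per original female
from adult emergence:

* the one-phase ("current") model drives egg timing directly off the
  female aging clock — daily eggs are
  ``F(T_i)·[E(Px_i) − E(Px_{i−1})]·S(Px_i)``;
* the two-phase model separates a pre-oviposition phase from the
  oviposition phase.  A pre-oviposition clock (PDRM) advances a
  completion distribution (PCDM); the fraction completing on day *i*
  enters oviposition on day *i+1* as its own cohort, whose eggs follow
  the oviposition-phase distribution (OORM) on a clock driven by the
  oviposition-phase rate (ODRM).  Survival always uses the aging clock
  counted from emergence.

Time step is one calendar day throughout; all outputs are per original
female of the emerging cohort, so lifetime totals are bounded by the
fecundity curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agedist import survival_prop, weibull2_cdf, weibull3_cdf
from .params import ParameterSet
from .thermal import aging_rate, fecundity, ovi_rate, preovi_rate

__all__ = [
    "CohortState",
    "accumulate_physio_age",
    "simulate_current_om",
    "simulate_two_phase_om",
    "egg_surface",
    "compare_observed",
    "lifetime_eggs",
]

#: survival level below which a cohort run terminates early
STOP_SURVIVAL = 1e-6

_COLUMNS = [
    "day",
    "temperature_C",
    "aging_px",
    "survival",
    "preovi_px",
    "completed_frac",
    "daily_eggs",
    "cum_eggs",
]


@dataclass
class CohortState:
    """Ledger entry: a fraction of females that entered oviposition
    together, carrying its own oviposition-phase physiological age."""

    entry_day: int
    fraction: float
    ovi_age: float
    prev_cdf: float


def accumulate_physio_age(
    rate_model: Callable[[np.ndarray], np.ndarray], temperatures: Sequence[float]
) -> np.ndarray:
    """Physiological age after each day: running sum of daily rates.

    ``Px_0 = 0`` is implicit; the returned array holds ``Px_1 … Px_n``
    with ``Px_i = Px_{i−1} + D(T_i)·1 day``.
    """
    T = np.asarray(temperatures, dtype=float)
    if T.size == 0:
        return np.zeros(0)
    return np.cumsum(np.asarray(rate_model(T), dtype=float))


def _check_series(temperatures) -> np.ndarray:
    T = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if T.size < 1:
        raise ValueError("temperature series must contain at least one day")
    return T


def _truncate(survival: np.ndarray, stop: float) -> int:
    # survival is non-increasing; keep days down to the stop level but
    # always at least one.
    return max(1, int(np.sum(survival >= stop)))


def simulate_current_om(
    params: ParameterSet,
    temperatures: Sequence[float],
    stop_survival: float = STOP_SURVIVAL,
) -> pd.DataFrame:
    """One-phase oviposition model over a daily temperature series.

    Returns one row per day (1-based from emergence) with the aging
    physiological age, survival, daily and cumulative eggs per original
    female.  The run stops early once survival falls below
    ``stop_survival``.
    """
    T = _check_series(temperatures)
    px = accumulate_physio_age(lambda t: aging_rate(params.aging_female, t), T)
    surv = survival_prop(params.survival_female, px)
    n = _truncate(surv, stop_survival)
    T, px, surv = T[:n], px[:n], surv[:n]

    cdf = weibull3_cdf(params.orm, px)
    delta = np.diff(np.concatenate([[0.0], cdf]))
    daily = fecundity(params.fecundity, T) * delta * surv
    return pd.DataFrame(
        {
            "day": np.arange(1, n + 1),
            "temperature_C": T,
            "aging_px": px,
            "survival": surv,
            "preovi_px": np.nan,
            "completed_frac": np.nan,
            "daily_eggs": daily,
            "cum_eggs": np.cumsum(daily),
        },
        columns=_COLUMNS,
    )


def simulate_two_phase_om(
    params: ParameterSet,
    temperatures: Sequence[float],
    stop_survival: float = STOP_SURVIVAL,
    return_ledger: bool = False,
):
    """Two-phase oviposition model over a daily temperature series.

    The pre-oviposition clock advances by the PDRM rate; the fraction of
    females completing pre-oviposition on day *i* (daily increment of
    the PCDM) enters oviposition on day *i+1* as a cohort.  Each
    cohort's oviposition-phase age advances by the ODRM rate — but only
    on days whose temperature lies inside the fecundity support, since
    the empirical ODRM curve was fitted on 16.7–34.9 °C data and
    diverges outside it.  A cohort's egg capacity is the fecundity at
    its entry-day temperature.  Survival multiplies in on the aging
    clock counted from emergence.

    With ``return_ledger=True`` also returns the final list of
    :class:`CohortState` entries.
    """
    T = _check_series(temperatures)
    px = accumulate_physio_age(lambda t: aging_rate(params.aging_female, t), T)
    surv = survival_prop(params.survival_female, px)
    n = _truncate(surv, stop_survival)
    T, px, surv = T[:n], px[:n], surv[:n]

    pre_px = accumulate_physio_age(lambda t: preovi_rate(params.pdrm, t), T)
    comp_cdf = weibull3_cdf(params.pcdm, pre_px)
    completed = np.diff(np.concatenate([[0.0], comp_cdf]))

    # Oviposition-phase clock, gated to the fecundity support.
    gate = (T > params.fecundity.T_L) & (T < params.fecundity.T_H)
    rate_o = np.zeros(n)
    if gate.any():
        # development cannot run backwards: clamp any negative rate to zero
        rate_o[gate] = np.maximum(ovi_rate(params.odrm, T[gate]), 0.0)
    G = np.concatenate([[0.0], np.cumsum(rate_o)])  # G[i] = ovi clock after day i

    entries = np.nonzero(completed > 0)[0] + 1  # completion day i (1-based)
    entries = entries[entries + 1 <= n]  # cohorts entering beyond the run drop out
    daily = np.zeros(n)
    ledger: list[CohortState] = []
    if entries.size:
        entry_days = entries + 1
        fractions = completed[entries - 1]
        caps = fecundity(params.fecundity, T[entry_days - 1])
        # ages[k, t] = cohort k's ovi age after day t+1 (0 before entry)
        ages = np.maximum(G[None, 1:] - G[entry_days - 1, None], 0.0)
        prev = np.maximum(G[None, :-1] - G[entry_days - 1, None], 0.0)
        cdf_now = weibull2_cdf(params.oorm, ages)
        cdf_prev = weibull2_cdf(params.oorm, prev)
        per_cohort = (fractions * caps)[:, None] * (cdf_now - cdf_prev)
        daily = per_cohort.sum(axis=0) * surv
        ledger = [
            CohortState(
                entry_day=int(e),
                fraction=float(f),
                ovi_age=float(a),
                prev_cdf=float(c),
            )
            for e, f, a, c in zip(entry_days, fractions, ages[:, -1], cdf_now[:, -1])
        ]

    out = pd.DataFrame(
        {
            "day": np.arange(1, n + 1),
            "temperature_C": T,
            "aging_px": px,
            "survival": surv,
            "preovi_px": pre_px,
            "completed_frac": completed,
            "daily_eggs": daily,
            "cum_eggs": np.cumsum(daily),
        },
        columns=_COLUMNS,
    )
    if return_ledger:
        return out, ledger
    return out


_MODELS = {
    "current": simulate_current_om,
    "two_phase": simulate_two_phase_om,
}


def egg_surface(
    params: ParameterSet,
    model: str = "two_phase",
    t_grid: Sequence[float] | None = None,
    horizon: int = 300,
) -> pd.DataFrame:
    """Daily egg production at each constant temperature of a grid.

    One constant-temperature simulation per grid point (default integer
    10–40 °C), each ``horizon`` days long; runs that terminate early are
    zero-padded.  Returns a long DataFrame (``temperature_C``, ``day``,
    ``daily_eggs``).
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1 day")
    if t_grid is None:
        t_grid = np.arange(10.0, 41.0)
    sim = _MODELS[model]
    frames = []
    for temp in t_grid:
        df = sim(params, np.full(horizon, float(temp)))
        daily = np.zeros(horizon)
        daily[: len(df)] = df["daily_eggs"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": float(temp),
                    "day": np.arange(1, horizon + 1),
                    "daily_eggs": daily,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lifetime_eggs(sim: pd.DataFrame) -> float:
    """Total eggs per original female over a simulated run."""
    return float(sim["daily_eggs"].sum())


def compare_observed(sim, observed) -> float:
    """Pearson r between cumulative simulated and observed egg curves.

    Both series are aligned at emergence (day 1) and compared over their
    common day range, after transforming to cumulative sums.  Requires
    at least three common days; a constant cumulative series (no eggs at
    all) leaves the correlation undefined and raises ``ValueError``.
    """
    if isinstance(sim, pd.DataFrame):
        sim = sim["daily_eggs"].to_numpy()
    sim = np.asarray(sim, dtype=float)
    observed = np.asarray(observed, dtype=float)
    m = min(sim.size, observed.size)
    if m < 3:
        raise ValueError("need at least 3 common days to correlate")
    cs, co = np.cumsum(sim[:m]), np.cumsum(observed[:m])
    if np.ptp(cs) == 0 or np.ptp(co) == 0:
        raise ValueError("constant cumulative series: correlation undefined")
    return float(stats.pearsonr(cs, co).statistic)
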