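"""Life-table reduction and model fitting.

Turns individual female records (rearing temperature, longevity, daily
egg counts) into the summaries and normalized age distributions that the
component models are fitted to:

* per-temperature means of longevity, fecundity, APOP and AOP;
* onset detection — the first day a female lays a significant number
  (> 5) of eggs with further laying soon after, defining APOP/AOP;
* physiological-age normalization — each individual's day count divided
  by the per-temperature mean of a reference period, pooled across
  temperatures and paired with an empirical proportion;
* ordinary least squares for the degree-day regressions and nonlinear
  least squares for every thermal-response and Weibull age model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .agedist import Weibull2Params, Weibull3Params
from .thermal import (
    AgingParams,
    Briere2Params,
    FecundityParams,
    LinearRateParams,
    OdrmParams,
)

__all__ = [
    "FemaleRecord",
    "FitError",
    "FitResult",
    "summarize",
    "detect_onset",
    "assign_onsets",
    "normalize_ages",
    "fit_linear",
    "fit_nonlinear",
]


@dataclass
class FemaleRecord:
    """One individual's life-table row.

    ``eggs`` is indexed by day since emergence (day 1 = first full day);
    its length never exceeds ``longevity``.  ``apop`` is the first
    sustained laying day (1-based); ``aop`` the span from that day to
    the last laying day, inclusive.
    """

    id: str
    temperature: float
    longevity: int
    eggs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sex: str = "female"
    apop: int | None = None
    aop: int | None = None

    def __post_init__(self):
        self.longevity = int(self.longevity)
        if self.longevity < 1:
            raise ValueError(f"{self.id}: longevity must be >= 1 day")
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.id}: sex must be 'female' or 'male'")
        self.eggs = np.asarray(self.eggs, dtype=float)
        if self.eggs.size > self.longevity:
            raise ValueError(
                f"{self.id}: egg series longer than longevity "
                f"({self.eggs.size} > {self.longevity})"
            )
        if np.any(self.eggs < 0):
            raise ValueError(f"{self.id}: negative egg counts")
        if self.apop is not None and self.aop is not None:
            if self.apop + self.aop - 1 > self.longevity:
                raise ValueError(
                    f"{self.id}: oviposition window exceeds longevity"
                )

    @property
    def lifetime_eggs(self) -> float:
        return float(self.eggs.sum())


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class FitResult:
    """Fitted parameters with goodness of fit."""

    params: object
    r_squared: float
    converged: bool
    n_points: int


def _se(x: np.ndarray) -> float:
    # Standard error of the mean; NaN flags an undefined SE (n = 1).
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def summarize(records: Iterable[FemaleRecord]) -> pd.DataFrame:
    """Per-(temperature, sex) summary: n, mean/SE/median longevity,
    mean/SE lifetime fecundity, and mean APOP/AOP over ovipositing females.

    Raises ``ValueError`` on an empty record set.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    keyed: dict[tuple[float, str], list[FemaleRecord]] = {}
    for r in records:
        keyed.setdefault((r.temperature, r.sex), []).append(r)
    for (temp, sex), group in sorted(keyed.items()):
        longev = np.array([r.longevity for r in group], dtype=float)
        row = {
            "temperature_C": temp,
            "sex": sex,
            "n": len(group),
            "longevity_mean": float(longev.mean()),
            "longevity_se": _se(longev),
            "longevity_median": float(np.median(longev)),
        }
        if sex == "female":
            fec = np.array([r.lifetime_eggs for r in group])
            row["fecundity_mean"] = float(fec.mean())
            row["fecundity_se"] = _se(fec)
            ovi = [r for r in group if r.apop is not None]
            row["n_ovipositing"] = len(ovi)
            if ovi:
                apops = np.array([r.apop for r in ovi], dtype=float)
                row["apop_mean"] = float(apops.mean())
                aops = np.array(
                    [r.aop for r in ovi if r.aop is not None], dtype=float
                )
                row["aop_mean"] = float(aops.mean()) if aops.size else float("nan")
            else:
                row["apop_mean"] = float("nan")
                row["aop_mean"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def detect_onset(eggs: Sequence[float], threshold: float = 5.0, window: int = 7):
    """First sustained laying day, or ``None``.

    Returns the first (1-based) day with more than ``threshold`` eggs that
    is followed by at least one further laying day within the next
    ``window`` days — sporadic single bursts do not count as onset.
    """
    eggs = np.asarray(eggs, dtype=float)
    candidates = np.nonzero(eggs > threshold)[0]
    for i in candidates:
        if np.any(eggs[i + 1 : i + 1 + window] > 0):
            return int(i) + 1
    return None


def assign_onsets(
    records: Iterable[FemaleRecord], threshold: float = 5.0, window: int = 7
) -> list[FemaleRecord]:
    """Fill ``apop``/``aop`` from each female's egg series where unset.

    AOP runs from the onset day to the last laying day, inclusive.
    Records already carrying an onset are left untouched.
    """
    out = []
    for r in records:
        if r.sex == "female" and r.apop is None and r.eggs.size:
            onset = detect_onset(r.eggs, threshold=threshold, window=window)
            if onset is not None:
                last = int(np.nonzero(r.eggs > 0)[0][-1]) + 1
                r = FemaleRecord(
                    id=r.id,
                    temperature=r.temperature,
                    longevity=r.longevity,
                    eggs=r.eggs,
                    sex=r.sex,
                    apop=onset,
                    aop=last - onset + 1,
                )
        out.append(r)
    return out


def _reference_means(groups, kind) -> dict[float, float]:
    ref = {}
    for temp, group in groups.items():
        if kind in ("survival", "oviposition"):
            vals = [r.longevity for r in group]
        elif kind == "completion":
            vals = [r.apop for r in group if r.apop is not None]
        else:  # phase_oviposition
            vals = [r.aop for r in group if r.aop is not None]
        if vals:
            ref[temp] = float(np.mean(vals))
    return ref


def normalize_ages(
    records: Iterable[FemaleRecord],
    kind: str,
    reference: dict[float, float] | None = None,
) -> pd.DataFrame:
    """Pooled normalized age-distribution points for one fit.

    ``kind`` selects both the day counter and the empirical proportion:

    ==================  ==========================  =========================
    kind                age axis (days / reference)  proportion
    ==================  ==========================  =========================
    survival            day / mean longevity         fraction still alive
    oviposition         day / mean longevity         cumulative egg fraction
    completion          APOP / mean APOP             fraction of layers begun
    phase_oviposition   phase day / mean AOP         cumulative egg fraction
    ==================  ==========================  =========================

    ``reference`` optionally overrides the per-temperature mean used as
    the normalizer (e.g. model-predicted periods); by default the
    empirical mean of the corresponding period is used.  A zero or
    missing reference mean for a represented temperature is an error.

    Returns a DataFrame with columns ``physio_age``, ``proportion``,
    ``source_temperature``.
    """
    if kind not in ("survival", "oviposition", "completion", "phase_oviposition"):
        raise ValueError(f"unknown kind {kind!r}")
    groups: dict[float, list[FemaleRecord]] = {}
    for r in records:
        groups.setdefault(r.temperature, []).append(r)
    if reference is None:
        reference = _reference_means(groups, kind)

    frames = []
    for temp, group in sorted(groups.items()):
        ref = reference.get(temp)
        ages, props = _empirical_curve(group, kind)
        if ages.size == 0:
            continue
        if ref is None or not ref > 0:
            raise ValueError(
                f"no positive reference mean for temperature {temp} ({kind})"
            )
        frames.append(
            pd.DataFrame(
                {
                    "physio_age": ages / ref,
                    "proportion": props,
                    "source_temperature": temp,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["physio_age", "proportion", "source_temperature"]
        )
    return pd.concat(frames, ignore_index=True)


def _empirical_curve(group, kind):
    """Per-temperature (day, proportion) curve, in days."""
    if kind == "survival":
        longev = np.array([r.longevity for r in group], dtype=float)
        days = np.arange(1, int(longev.max()) + 1, dtype=float)
        props = np.array([(longev >= d).mean() for d in days])
        return days, props
    if kind == "completion":
        apops = np.array(
            [r.apop for r in group if r.apop is not None], dtype=float
        )
        if apops.size == 0:
            return np.zeros(0), np.zeros(0)
        days = np.unique(apops)
        props = np.array([(apops <= d).mean() for d in days])
        return days, props
    if kind == "oviposition":
        maxlen = max((r.eggs.size for r in group), default=0)
        if maxlen == 0:
            return np.zeros(0), np.zeros(0)
        total = np.zeros(maxlen)
        for r in group:
            total[: r.eggs.size] += r.eggs
        if total.sum() <= 0:
            return np.zeros(0), np.zeros(0)
        last = int(np.nonzero(total > 0)[0][-1]) + 1
        days = np.arange(1, last + 1, dtype=float)
        props = np.cumsum(total[:last]) / total.sum()
        return days, props
    # phase_oviposition: day counter restarts at each female's onset day
    layers = [r for r in group if r.apop is not None]
    if not layers:
        return np.zeros(0), np.zeros(0)
    maxphase = max(r.eggs.size - r.apop + 1 for r in layers)
    if maxphase < 1:
        return np.zeros(0), np.zeros(0)
    total = np.zeros(maxphase)
    for r in layers:
        phase = r.eggs[r.apop - 1 :]
        total[: phase.size] += phase
    if total.sum() <= 0:
        return np.zeros(0), np.zeros(0)
    last = int(np.nonzero(total > 0)[0][-1]) + 1
    days = np.arange(1, last + 1, dtype=float)
    props = np.cumsum(total[:last]) / total.sum()
    return days, props


def fit_linear(
    temperatures: Sequence[float],
    rates: Sequence[float],
    region: tuple[float, float] | None = None,
) -> tuple[LinearRateParams, float]:
    """OLS of rate on temperature over a linear region.

    ``region`` is an inclusive (low, high) temperature window; at least
    three points must fall inside it.  Returns the fitted line and the
    Pearson correlation r.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(rates, dtype=float)
    if region is not None:
        keep = (T >= region[0]) & (T <= region[1])
        T, y = T[keep], y[keep]
    if T.size < 3:
        raise ValueError(f"need >= 3 points in region, got {T.size}")
    res = stats.linregress(T, y)
    return LinearRateParams(slope_a=res.slope, intercept_b=res.intercept), float(
        res.rvalue
    )


# --- nonlinear fitting ------------------------------------------------------

def _model_aging(T, r0, TH, c):
    return r0 + np.exp((T - TH) / c)


def _model_fecundity(T, a, TL, TH):
    return np.maximum(a * (T - TL) * (TH - T), 0.0)


def _model_briere2(T, a, TL, TH, m):
    base = np.maximum(TH - T, 0.0)
    return np.maximum(a * T * (T - TL) * np.power(base, 1.0 / m), 0.0)


def _model_weibull2_surv(x, a, b):
    return np.exp(-np.power(x / a, b))


def _model_weibull2_cdf(x, a, b):
    return -np.expm1(-np.power(x / a, b))


def _model_weibull3_cdf(x, g, eta, b):
    return -np.expm1(-np.power(np.maximum(x - g, 0.0) / eta, b))


def _init_scale(x, y, level):
    """Empirical quantile of a scattered cumulative curve: smallest x
    whose proportion reaches ``level``."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    hit = np.nonzero(ys >= level)[0] if level > 0.5 else np.nonzero(ys <= level)[0]
    if hit.size:
        return float(xs[hit[0]])
    return float(np.median(xs))


def _fit_odrm(x, y):
    # The four-term curve is linear in its coefficients: solve exactly.
    # Column norms span ~30 orders of magnitude (e^T vs e^-T), so scale
    # to unit columns before the least-squares solve.
    design = np.column_stack(
        [np.ones_like(x), np.exp(x), x**-2.0, np.exp(-x)]
    )
    norms = np.linalg.norm(design, axis=0)
    coef, *_ = np.linalg.lstsq(design / norms, y, rcond=None)
    coef = coef / norms
    fitted = design @ coef
    return OdrmParams(*(float(v) for v in coef)), fitted, True


_KIND_ALIASES = {
    "orm": "weibull3",
    "pcdm": "weibull3",
    "oorm": "weibull2",
    "pdrm": "briere2",
}

_N_PARAMS = {
    "aging": 3,
    "fecundity": 3,
    "briere2": 4,
    "odrm": 4,
    "survival": 2,
    "weibull2": 2,
    "weibull3": 3,
}


def fit_nonlinear(kind: str, x, y, p0=None) -> FitResult:
    """Least-squares fit of one component model to (x, y) points.

    ``kind`` is one of ``aging``, ``fecundity``, ``briere2``/``pdrm``,
    ``odrm``, ``survival``, ``weibull2``/``oorm``, ``weibull3``/``orm``/
    ``pcdm``.  Initialisation is deterministic: temperature limits are
    seeded 1 °C outside the observed support, Weibull scales at the
    empirical 63rd percentile of the curve, shapes at 1.5.  ``p0``
    overrides it.  Raises :class:`FitError` (carrying the last iterate)
    on non-convergence.
    """
    kind = _KIND_ALIASES.get(kind, kind)
    if kind not in _N_PARAMS:
        raise ValueError(f"unknown model kind {kind!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size <= _N_PARAMS[kind]:
        raise ValueError(
            f"need more points than parameters ({_N_PARAMS[kind]}) for {kind}"
        )

    if kind == "odrm":
        params, fitted, ok = _fit_odrm(x, y)
        return FitResult(params, _r2(y, fitted), ok, x.size)

    eps = 1e-9
    if kind == "aging":
        model = _model_aging
        r0 = 0.9 * max(float(y.min()), eps)
        c0 = 5.0
        th0 = float(x.max()) - c0 * np.log(max(float(y.max()) - r0, 1e-8))
        default_p0 = [r0, th0, c0]
        lo = [eps, float(x.max()), 0.1]
        hi = [float(y.max()), 150.0, 50.0]
    elif kind == "fecundity":
        model = _model_fecundity
        tl0, th0 = float(x.min()) - 1.0, float(x.max()) + 1.0
        a0 = float(y.max()) / max(((th0 - tl0) / 2.0) ** 2, eps)
        default_p0 = [a0, tl0, th0]
        lo = [eps, 0.0, float(x.max())]
        hi = [np.inf, float(x.min()), 60.0]
    elif kind == "briere2":
        model = _model_briere2
        tl0, th0, m0 = float(x.min()) - 1.0, float(x.max()) + 1.0, 2.0
        xm = float(x[np.argmax(y)])
        denom = max(xm * (xm - tl0) * (th0 - xm) ** (1.0 / m0), eps)
        default_p0 = [float(y.max()) / denom, tl0, th0, m0]
        lo = [eps, 0.0, float(x.max()), 0.2]
        hi = [np.inf, float(x.min()), 60.0, 20.0]
    elif kind == "survival":
        model = _model_weibull2_surv
        default_p0 = [_init_scale(x, y, 1.0 - np.exp(-1.0)), 1.5]
        lo, hi = [eps, 0.05], [np.inf, 50.0]
    elif kind == "weibull2":
        model = _model_weibull2_cdf
        default_p0 = [_init_scale(x, y, 1.0 - 1.0 / np.e), 1.5]
        lo, hi = [eps, 0.05], [np.inf, 50.0]
    else:  # weibull3
        model = _model_weibull3_cdf
        positive = x[y > 0]
        g0 = float(positive.min()) * 0.9 if positive.size else 0.0
        scale0 = max(_init_scale(x, y, 1.0 - 1.0 / np.e) - g0, 10 * eps)
        default_p0 = [g0, scale0, 1.5]
        lo, hi = [0.0, eps, 0.05], [float(x.max()), np.inf, 50.0]

    start = np.asarray(p0 if p0 is not None else default_p0, dtype=float)
    start = np.clip(start, lo, hi)

    def residual(p):
        return model(x, *p) - y

    res = optimize.least_squares(
        residual, start, bounds=(lo, hi), xtol=1e-13, ftol=1e-13, gtol=1e-13
    )
    if not res.success:
        raise FitError(
            f"{kind} fit did not converge: {res.message}", last_params=res.x
        )
    params = _wrap_params(kind, res.x)
    return FitResult(params, _r2(y, model(x, *res.x)), True, x.size)


def _r2(y, fitted) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _wrap_params(kind, p):
    if kind == "aging":
        return AgingParams(r0=float(p[0]), T_H=float(p[1]), c=float(p[2]))
    if kind == "fecundity":
        return FecundityParams(alpha_f=float(p[0]), T_L=float(p[1]), T_H=float(p[2]))
    if kind == "briere2":
        return Briere2Params(
            alpha_p=float(p[0]), T_L=float(p[1]), T_H=float(p[2]), m=float(p[3])
        )
    if kind in ("survival", "weibull2"):
        return Weibull2Params(alpha=float(p[0]), beta=float(p[1]))
    return Weibull3Params(gamma=float(p[0]), eta=float(p[1]), beta=float(p[2]))
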