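"""Model/Results interface tying the fitting pipeline together.

:class:`ReproductionModel` is built from individual life-table data and
its :meth:`~ReproductionModel.fit` estimates the complete suite of
component models — aging and survival curves per sex, the fecundity
curve, and both oviposition parameterisations (one-phase ORM;
two-phase PDRM/PCDM/ODRM/OORM) — returning a
:class:`ReproductionResults` that carries the assembled
:class:`~ovimodel.params.ParameterSet`, per-fit goodness of fit, the
degree-day regressions, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lifetable import (
    FemaleRecord,
    FitResult,
    assign_onsets,
    fit_linear,
    fit_nonlinear,
    normalize_ages,
    summarize,
)
from .params import ParameterSet
from .thermal import LinearRateParams, ldt_tc

__all__ = ["ReproductionModel", "ReproductionResults"]

#: default temperature windows (°C) over which the degree-day rates are linear
LINEAR_REGIONS = {
    "aging": (18.8, 34.9),
    "apop": (16.7, 32.0),
    "aop": (18.8, 32.0),
}


class ReproductionModel:
    """Temperature-dependent reproduction model for adult fruit flies.

    Parameters
    ----------
    records
        Individual life-table rows.  Onset days (APOP/AOP) are detected
        from the egg series wherever a record does not already carry
        them, using the >``onset_threshold``-eggs-with-follow-up rule.
    onset_threshold, onset_window
        Daily egg count that marks sustained laying, and the number of
        following days in which at least one more laying day must occur.
    """

    def __init__(
        self,
        records: Iterable[FemaleRecord],
        onset_threshold: float = 5.0,
        onset_window: int = 7,
    ):
        self.records = assign_onsets(
            list(records), threshold=onset_threshold, window=onset_window
        )
        if not self.records:
            raise ValueError("no records supplied")

    @classmethod
    def from_dataframe(
        cls, females: pd.DataFrame, eggs: pd.DataFrame | None = None, **kwargs
    ) -> "ReproductionModel":
        """Build from the life-table CSV dialect loaded into DataFrames.

        ``females`` needs columns ``id, temperature_C, sex,
        longevity_days``; ``eggs`` needs ``id, day, eggs`` (one row per
        laying day; missing days are zero).
        """
        from .io import records_from_frames

        return cls(records_from_frames(females, eggs), **kwargs)

    @classmethod
    def from_csv(
        cls, females_path, eggs_path=None, **kwargs
    ) -> "ReproductionModel":
        from .io import read_lifetable

        return cls(read_lifetable(females_path, eggs_path), **kwargs)

    def fit(self, linear_regions: dict | None = None) -> "ReproductionResults":
        """Estimate every component model from the records.

        Thermal-response curves (aging, fecundity, pre-oviposition and
        oviposition-phase rates) are fitted to per-temperature means;
        age distributions (survival, ORM, PCDM, OORM) to pooled
        per-individual points normalized by the per-temperature mean of
        the matching period.  Degree-day lines are fitted over
        ``linear_regions`` (defaults to the study's windows) when at
        least three temperatures fall inside.
        """
        regions = dict(LINEAR_REGIONS)
        if linear_regions:
            regions.update(linear_regions)
        females = [r for r in self.records if r.sex == "female"]
        males = [r for r in self.records if r.sex == "male"]
        if not females:
            raise ValueError("no female records: nothing to fit")
        table = summarize(self.records)
        fsum = table[table["sex"] == "female"]

        fits: dict[str, FitResult] = {}
        temps = fsum["temperature_C"].to_numpy()
        aging_rates = 1.0 / fsum["longevity_mean"].to_numpy()
        fits["aging_female"] = fit_nonlinear("aging", temps, aging_rates)
        surv_pts = normalize_ages(females, "survival")
        fits["survival_female"] = fit_nonlinear(
            "survival", surv_pts["physio_age"], surv_pts["proportion"]
        )
        if males:
            msum = table[table["sex"] == "male"]
            fits["aging_male"] = fit_nonlinear(
                "aging",
                msum["temperature_C"].to_numpy(),
                1.0 / msum["longevity_mean"].to_numpy(),
            )
            mpts = normalize_ages(males, "survival")
            fits["survival_male"] = fit_nonlinear(
                "survival", mpts["physio_age"], mpts["proportion"]
            )

        laying = fsum[fsum["fecundity_mean"] > 0]
        fits["fecundity"] = fit_nonlinear(
            "fecundity",
            laying["temperature_C"].to_numpy(),
            laying["fecundity_mean"].to_numpy(),
        )
        orm_pts = normalize_ages(females, "oviposition")
        fits["orm"] = fit_nonlinear(
            "weibull3", orm_pts["physio_age"], orm_pts["proportion"]
        )

        ovi = fsum[fsum["apop_mean"] > 0]
        fits["pdrm"] = fit_nonlinear(
            "briere2",
            ovi["temperature_C"].to_numpy(),
            1.0 / ovi["apop_mean"].to_numpy(),
        )
        pcdm_pts = normalize_ages(females, "completion")
        fits["pcdm"] = fit_nonlinear(
            "weibull3", pcdm_pts["physio_age"], pcdm_pts["proportion"]
        )
        fits["odrm"] = fit_nonlinear(
            "odrm",
            ovi["temperature_C"].to_numpy(),
            1.0 / ovi["aop_mean"].to_numpy(),
        )
        oorm_pts = normalize_ages(females, "phase_oviposition")
        fits["oorm"] = fit_nonlinear(
            "weibull2", oorm_pts["physio_age"], oorm_pts["proportion"]
        )

        linear: dict[str, tuple[LinearRateParams, float]] = {}
        for name, (T, rate) in {
            "female_longevity": (temps, aging_rates),
            "apop": (ovi["temperature_C"].to_numpy(), 1.0 / ovi["apop_mean"].to_numpy()),
            "aop": (ovi["temperature_C"].to_numpy(), 1.0 / ovi["aop_mean"].to_numpy()),
        }.items():
            region = regions["aging" if name == "female_longevity" else name]
            inside = (T >= region[0]) & (T <= region[1])
            if inside.sum() >= 3:
                linear[name] = fit_linear(T, rate, region=region)
        if males:
            T = msum["temperature_C"].to_numpy()
            rate = 1.0 / msum["longevity_mean"].to_numpy()
            inside = (T >= regions["aging"][0]) & (T <= regions["aging"][1])
            if inside.sum() >= 3:
                linear["male_longevity"] = fit_linear(T, rate, region=regions["aging"])

        params = ParameterSet(
            aging_female=fits["aging_female"].params,
            survival_female=fits["survival_female"].params,
            fecundity=fits["fecundity"].params,
            orm=fits["orm"].params,
            pdrm=fits["pdrm"].params,
            pcdm=fits["pcdm"].params,
            odrm=fits["odrm"].params,
            oorm=fits["oorm"].params,
            aging_male=fits["aging_male"].params if males else None,
            survival_male=fits["survival_male"].params if males else None,
        )
        return ReproductionResults(
            params=params, fits=fits, linear=linear, table=table
        )


@dataclass
class ReproductionResults:
    """Fitted parameter set plus diagnostics.

    Attributes
    ----------
    params : ParameterSet
        The assembled estimates, ready for the simulators.
    fits : dict
        Per-component :class:`~ovimodel.lifetable.FitResult` (r², n,
        convergence flag).
    linear : dict
        Degree-day regressions fitted in their linear regions:
        name -> (LinearRateParams, Pearson r).
    table : pandas.DataFrame
        The per-temperature life-table summary the fits used.
    """

    params: ParameterSet
    fits: dict
    linear: dict
    table: pd.DataFrame

    def degree_day(self) -> pd.DataFrame:
        """LDT (°C) and TC (degree-days) derived from each linear fit."""
        rows = []
        for name, (lp, r) in self.linear.items():
            ldt, tc = ldt_tc(lp)
            rows.append(
                {
                    "trait": name,
                    "slope_a": lp.slope_a,
                    "intercept_b": lp.intercept_b,
                    "r": r,
                    "ldt_C": ldt,
                    "tc_dd": tc,
                }
            )
        return pd.DataFrame(rows)

    def simulate(self, temperatures: Sequence[float], model: str = "two_phase"):
        """Run an oviposition simulator with the fitted parameters."""
        from .simulate import simulate_current_om, simulate_two_phase_om

        sim = simulate_two_phase_om if model == "two_phase" else simulate_current_om
        return sim(self.params, temperatures)

    def save_params(self, path) -> None:
        self.params.to_json(Path(path))

    def summary(self) -> str:
        """Readable account of every fitted component."""
        lines = ["Temperature-dependent reproduction model", "=" * 44]
        order = [
            ("aging_female", "Aging rate, female  A(T) = r0 + exp((T-T_H)/c)"),
            ("aging_male", "Aging rate, male"),
            ("survival_female", "Survival, female  S(Px) = exp(-(Px/alpha)^beta)"),
            ("survival_male", "Survival, male"),
            ("fecundity", "Fecundity  F(T) = alpha_f (T-T_L)(T_H-T)"),
            ("orm", "Cumulative oviposition, whole life (ORM)"),
            ("pdrm", "Pre-oviposition rate (PDRM, Briere-2)"),
            ("pcdm", "Pre-oviposition completion (PCDM)"),
            ("odrm", "Oviposition-phase rate (ODRM)"),
            ("oorm", "Cumulative oviposition, phase (OORM)"),
        ]
        for key, title in order:
            if key not in self.fits:
                continue
            fr = self.fits[key]
            pairs = ", ".join(
                f"{k}={v:.6g}" for k, v in vars(fr.params).items()
            )
            lines.append(f"{title}")
            lines.append(
                f"    {pairs}   [r^2={fr.r_squared:.3f}, n={fr.n_points}]"
            )
        if self.linear:
            lines.append("Degree-day regressions (linear region)")
            for _, row in self.degree_day().iterrows():
                lines.append(
                    f"    {row['trait']}: rate = {row['slope_a']:.4f} T "
                    f"{row['intercept_b']:+.4f}  (r={row['r']:.2f}, "
                    f"LDT={row['ldt_C']:.1f} °C, TC={row['tc_dd']:.1f} DD)"
                )
        return "\n".join(lines)
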