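"""Synthetic individual-level life tables drawn from a known parameter set.

Inverts the normalization used in fitting: each female's death and
pre-oviposition completion are drawn on the physiological-age axis from
the survival and completion Weibulls, then converted to whole days with
the temperature-specific rate models.  Eggs are spread over the
oviposition phase by the daily increments of the oviposition-phase
distribution (OORM) under the ODRM clock.  Every fitting and simulation
stage of the package is therefore testable against known ground truth
without any external data.

Default conditions mirror the laboratory study: the six constant
temperatures at which eggs were laid, twenty females per temperature,
integer (multinomially resampled) daily egg counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agedist import weibull2_cdf
from .lifetable import FemaleRecord
from .params import ParameterSet
from .thermal import aging_rate, fecundity, ovi_rate, preovi_rate

__all__ = ["SynthConfig", "generate_cohort"]

#: rearing temperatures (°C) at which the study observed egg laying
STUDY_TEMPERATURES = (16.7, 18.8, 23.5, 28.1, 32.0, 34.9)


@dataclass
class SynthConfig:
    """Conditions for one synthetic cohort.

    ``egg_noise='multinomial'`` resamples each female's egg total
    multinomially over her laying days (integer counts, like the daily
    census of the experiment); ``'none'`` records the deterministic
    expected counts instead.
    """

    temperatures: Sequence[float] = STUDY_TEMPERATURES
    n_per_temperature: int = 20
    seed: int = 0
    egg_noise: str = "multinomial"
    max_days: int = 1000

    def __post_init__(self):
        if self.n_per_temperature < 0:
            raise ValueError("n_per_temperature must be >= 0")
        if self.egg_noise not in ("multinomial", "none"):
            raise ValueError("egg_noise must be 'multinomial' or 'none'")
        for t in self.temperatures:
            if not 0.0 < t < 45.0:
                raise ValueError(f"temperature {t} outside (0, 45) °C")


def generate_cohort(params: ParameterSet, config: SynthConfig) -> list[FemaleRecord]:
    """Generate individual females whose life tables follow ``params``.

    Per female at temperature T:

    * normalized death age ~ the survival Weibull; longevity is the age
      divided by the aging rate A(T), rounded up to whole days (the
      daily census records a female alive during day d with longevity d);
    * normalized completion age ~ the pre-oviposition completion
      Weibull; the completion day is the age divided by the
      pre-oviposition rate, rounded up, and laying starts the following
      day (APOP = that first laying day);
    * her full egg capacity F(T) is spread over the laying days by the
      oviposition-phase distribution increments under the ODRM clock,
      renormalized over the days she lives to see;
    * females at temperatures outside the fecundity support, or who die
      before completing pre-oviposition, lay nothing and carry no APOP.

    Reproducible: the same config (seed included) yields the same
    records.
    """
    rng = np.random.default_rng(config.seed)
    records: list[FemaleRecord] = []
    for T in config.temperatures:
        a_rate = aging_rate(params.aging_female, T)
        cap = fecundity(params.fecundity, T)
        dp = preovi_rate(params.pdrm, T)
        do = ovi_rate(params.odrm, T) if cap > 0 else 0.0
        for i in range(config.n_per_temperature):
            rid = f"T{T:g}_{i:04d}"
            death_age = params.survival_female.alpha * rng.weibull(
                params.survival_female.beta
            )
            longevity = min(
                max(1, math.ceil(death_age / a_rate)), config.max_days
            )
            comp_age = params.pcdm.gamma + params.pcdm.eta * rng.weibull(
                params.pcdm.beta
            )
            if cap <= 0 or dp <= 0 or do <= 0:
                records.append(
                    FemaleRecord(id=rid, temperature=T, longevity=longevity)
                )
                continue
            first_lay = math.ceil(comp_age / dp) + 1
            if first_lay > longevity:
                # mortality before oviposition: no eggs, no APOP
                records.append(
                    FemaleRecord(
                        id=rid,
                        temperature=T,
                        longevity=longevity,
                        eggs=np.zeros(longevity),
                    )
                )
                continue
            eggs = np.zeros(longevity)
            n_days = longevity - first_lay + 1
            ages = do * np.arange(0, n_days + 1)
            weights = np.diff(weibull2_cdf(params.oorm, ages))
            total_w = weights.sum()
            if total_w <= 0:
                records.append(
                    FemaleRecord(
                        id=rid, temperature=T, longevity=longevity, eggs=eggs
                    )
                )
                continue
            if config.egg_noise == "multinomial":
                counts = rng.multinomial(
                    int(round(cap)), weights / total_w
                ).astype(float)
            else:
                counts = cap * weights / total_w
            eggs[first_lay - 1 :] = counts
            laying = np.nonzero(eggs > 0)[0]
            if laying.size:
                last = int(laying[-1]) + 1
                apop, aop = first_lay, last - first_lay + 1
            else:
                apop, aop = None, None
            records.append(
                FemaleRecord(
                    id=rid,
                    temperature=T,
                    longevity=longevity,
                    eggs=eggs,
                    apop=apop,
                    aop=aop,
                )
            )
    return records
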