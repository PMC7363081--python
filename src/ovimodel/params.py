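"""Parameter bundles and their JSON serialisation.

A :class:`ParameterSet` holds every fitted constant the oviposition
simulators need: the male/female aging curves and survival Weibulls, the
fecundity curve, and the component models of the two competing
simulators (ORM for the one-phase model; PDRM/PCDM/ODRM/OORM for the
two-phase model).  The packaged default, :func:`default_parameters`,
carries the published estimates for the Taiwanese laboratory population
of *B. dorsalis*.

JSON layout: one object per component model, field names exactly as in
the dataclasses, e.g. ``{"fecundity": {"alpha_f": ..., "T_L": ...,
"T_H": ...}, "oorm": {"alpha": ..., "beta": ...}, ...}``.  Unknown
top-level keys are ignored on read so fit reports can carry extra
diagnostic blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .agedist import Weibull2Params, Weibull3Params
from .thermal import AgingParams, Briere2Params, FecundityParams, OdrmParams

__all__ = ["ParameterSet", "default_parameters"]

_FIELD_TYPES = {
    "aging_female": AgingParams,
    "aging_male": AgingParams,
    "survival_female": Weibull2Params,
    "survival_male": Weibull2Params,
    "fecundity": FecundityParams,
    "orm": Weibull3Params,
    "pdrm": Briere2Params,
    "pcdm": Weibull3Params,
    "odrm": OdrmParams,
    "oorm": Weibull2Params,
}

_REQUIRED = (
    "aging_female",
    "survival_female",
    "fecundity",
    "orm",
    "pdrm",
    "pcdm",
    "odrm",
    "oorm",
)


@dataclass
class ParameterSet:
    """Complete bundle of fitted constants for both oviposition models.

    The male components are optional: they describe male longevity only
    and no simulator consumes them, but the packaged default carries the
    published values.
    """

    aging_female: AgingParams
    survival_female: Weibull2Params
    fecundity: FecundityParams
    orm: Weibull3Params
    pdrm: Briere2Params
    pcdm: Weibull3Params
    odrm: OdrmParams
    oorm: Weibull2Params
    aging_male: AgingParams | None = None
    survival_male: Weibull2Params | None = None

    def to_dict(self) -> dict:
        out = {}
        for name in _FIELD_TYPES:
            value = getattr(self, name)
            if value is not None:
                out[name] = dataclasses.asdict(value)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        missing = [k for k in _REQUIRED if k not in data]
        if missing:
            raise ValueError(f"parameter file missing component(s): {missing}")
        kwargs = {}
        for name, typ in _FIELD_TYPES.items():
            if name in data:
                kwargs[name] = typ(**data[name])
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_parameters() -> ParameterSet:
    """Published parameter estimates for *B. dorsalis* (packaged default)."""
    text = (
        resources.files("ovimodel.data")
        .joinpath("bdorsalis_params.json")
        .read_text()
    )
    return ParameterSet.from_dict(json.loads(text))
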