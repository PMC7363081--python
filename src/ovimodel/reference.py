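"""Published per-temperature summary statistics for *B. dorsalis* adults.

The study reared adults at seven constant temperatures (13.5–34.9 °C)
and reported per-temperature means of longevity, lifetime fecundity and
the pre-oviposition/oviposition periods, plus the degree-day regressions
derived from them.  These printed summaries are the inputs from which
the linear and fecundity fits can be reproduced, so they ship with the
package as reference data.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["adult_summary", "oviposition_summary", "degree_day_summary"]


def _load() -> dict:
    text = (
        resources.files("ovimodel.data")
        .joinpath("bdorsalis_observed.json")
        .read_text()
    )
    return json.loads(text)


def adult_summary() -> pd.DataFrame:
    """Longevity and fecundity means (± SE, median) per rearing temperature.

    One row per constant temperature; females and males side by side.
    ``fecundity_mean`` is NaN at 13.5 °C, where no eggs were laid.
    """
    return pd.DataFrame(_load()["adult"])


def oviposition_summary() -> pd.DataFrame:
    """APOP/AOP/TPOP means per temperature, for ovipositing females only.

    APOP: days from emergence to first sustained laying; AOP: first to
    last laying day; TPOP: APOP plus the immature development period.
    """
    return pd.DataFrame(_load()["oviposition"])


def degree_day_summary() -> pd.DataFrame:
    """Published linear degree-day regressions (slope, intercept, LDT, TC).

    Note the printed thresholds were derived from unrounded regressions:
    recomputing −b/a from the rounded printed coefficients does not
    always reproduce the printed LDT (e.g. female longevity).
    """
    return pd.DataFrame(_load()["degree_day"])
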