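"""CSV dialects for life tables and temperature series.

Life tables travel as two comma-separated, headered, UTF-8 files:

* females: ``id, temperature_C, sex, longevity_days``
* eggs: ``id, day, eggs`` — one row per laying day, joined to females
  by ``id``; days without a row are zero.

Temperature series: ``day`` (or ISO-8601 ``date``) and ``mean_temp_C``.
Numbers are serialized with six significant digits so repeated runs on
identical inputs are byte-stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .lifetable import FemaleRecord

__all__ = [
    "read_lifetable",
    "write_lifetable",
    "records_from_frames",
    "read_temperature_series",
    "write_simulation",
]

FEMALE_COLUMNS = ["id", "temperature_C", "sex", "longevity_days"]
EGG_COLUMNS = ["id", "day", "eggs"]
FLOAT_FORMAT = "%.6g"


def _require_columns(df: pd.DataFrame, needed, what: str):
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def records_from_frames(
    females: pd.DataFrame, eggs: pd.DataFrame | None = None
) -> list[FemaleRecord]:
    """Validate and join the two tables into records.

    Unknown ids in the egg table, duplicate female ids, duplicate
    (id, day) rows, non-positive days, days beyond longevity and
    negative counts are all rejected with descriptive errors.
    """
    _require_columns(females, FEMALE_COLUMNS, "female table")
    if females["id"].duplicated().any():
        dupes = females.loc[females["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate female id(s): {dupes}")
    egg_map: dict[str, list[tuple[int, float]]] = {}
    if eggs is not None and len(eggs):
        _require_columns(eggs, EGG_COLUMNS, "egg table")
        known = set(females["id"].astype(str))
        unknown = sorted(set(eggs["id"].astype(str)) - known)
        if unknown:
            raise ValueError(f"egg rows for unknown female id(s): {unknown}")
        if eggs.duplicated(subset=["id", "day"]).any():
            dup = eggs[eggs.duplicated(subset=["id", "day"], keep=False)]
            raise ValueError(
                f"duplicate (id, day) egg rows: {dup[['id', 'day']].values.tolist()}"
            )
        if (eggs["eggs"] < 0).any():
            raise ValueError("negative egg counts in egg table")
        if (eggs["day"] < 1).any():
            raise ValueError("egg days must be >= 1")
        for rid, day, count in eggs[["id", "day", "eggs"]].itertuples(index=False):
            egg_map.setdefault(str(rid), []).append((int(day), float(count)))

    records = []
    for row in females.itertuples(index=False):
        rid = str(row.id)
        longevity = int(row.longevity_days)
        series = np.zeros(longevity)
        for day, count in egg_map.get(rid, []):
            if day > longevity:
                raise ValueError(
                    f"{rid}: egg row on day {day} beyond longevity {longevity}"
                )
            series[day - 1] = count
        records.append(
            FemaleRecord(
                id=rid,
                temperature=float(row.temperature_C),
                sex=str(row.sex),
                longevity=longevity,
                eggs=series if str(row.sex) == "female" else np.zeros(0),
            )
        )
    return records


def read_lifetable(females_path, eggs_path=None) -> list[FemaleRecord]:
    """Load life-table records from the CSV dialect."""
    females = pd.read_csv(females_path)
    eggs = pd.read_csv(eggs_path) if eggs_path is not None else None
    return records_from_frames(females, eggs)


def write_lifetable(
    records: Iterable[FemaleRecord], females_path, eggs_path
) -> None:
    """Write records in the same dialect ``read_lifetable`` consumes.

    Only positive egg days get a row; zero days are implicit.
    """
    records = list(records)
    females = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "temperature_C": [r.temperature for r in records],
            "sex": [r.sex for r in records],
            "longevity_days": [r.longevity for r in records],
        }
    )
    rows = []
    for r in records:
        for day in np.nonzero(r.eggs > 0)[0]:
            rows.append({"id": r.id, "day": int(day) + 1, "eggs": r.eggs[day]})
    eggs = pd.DataFrame(rows, columns=EGG_COLUMNS)
    females.to_csv(females_path, index=False, float_format=FLOAT_FORMAT)
    eggs.to_csv(eggs_path, index=False, float_format=FLOAT_FORMAT)


def read_temperature_series(path) -> np.ndarray:
    """Daily mean temperatures, ordered by ``day`` or ``date``."""
    df = pd.read_csv(path)
    if "mean_temp_C" not in df.columns:
        raise ValueError("temperature series: missing column 'mean_temp_C'")
    if "day" in df.columns:
        df = df.sort_values("day")
    elif "date" in df.columns:
        df = df.assign(date=pd.to_datetime(df["date"])).sort_values("date")
    else:
        raise ValueError("temperature series: need a 'day' or 'date' column")
    return df["mean_temp_C"].to_numpy(dtype=float)


def write_simulation(sim: pd.DataFrame, path) -> None:
    """Write a simulated day table as CSV with stable float formatting."""
    sim.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def sha256_digest(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
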