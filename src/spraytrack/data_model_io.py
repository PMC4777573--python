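"""Canonical data types and tabular I/O for sticky-trap and cage-experiment data.

The atoms of the pipeline are :class:`TrapRecord` (one sticky trap at one
collection) and :class:`CageRecord` (one cage x sex at one treatment).  Readers
accept delimited text (CSV) or spreadsheets (XLSX) with a configurable column
mapping; the default layout mirrors the field-study workbook sheet names
("Wild mosquitos", "Cage mosquitos").
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "CageRole",
    "Sex",
    "TrapRecord",
    "CageRecord",
    "TreatmentSchedule",
    "WeatherRecord",
    "SchemaError",
    "ValidationError",
    "read_trap_table",
    "write_trap_table",
    "read_cage_table",
    "write_cage_table",
    "read_weather_table",
    "write_weather_table",
    "read_schedule",
    "write_schedule",
    "site_mean_series",
    "trap_frame",
    "cage_frame",
]


class SchemaError(ValueError):
    """Raised when an input table does not expose the declared columns."""


class ValidationError(ValueError):
    """Raised when a row violates a record invariant."""


class Site(str, enum.Enum):
    TREATED = "treated"
    UNTREATED = "untreated"


class CageRole(str, enum.Enum):
    EXPOSED = "exposed"
    VALIDATION = "validation"
    CONTROL = "control"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class TrapRecord:
    """One sticky-trap x collection observation."""

    trap_id: str
    site: Site
    collection_index: int
    collection_date: _dt.date
    n_female: int
    n_male: int
    n_total: int
    water_leftover: float
    active: bool = True

    def __post_init__(self) -> None:
        if self.collection_index < 1:
            raise ValidationError(
                f"trap {self.trap_id}: collection_index must be >= 1, "
                f"got {self.collection_index}"
            )
        for field in ("n_female", "n_male", "n_total"):
            if getattr(self, field) < 0:
                raise ValidationError(
                    f"trap {self.trap_id} collection {self.collection_index}: "
                    f"negative count in {field}"
                )
        if self.n_total != self.n_female + self.n_male:
            raise ValidationError(
                f"trap {self.trap_id} collection {self.collection_index}: "
                f"n_total={self.n_total} != n_female+n_male="
                f"{self.n_female + self.n_male}"
            )
        if self.water_leftover < 0:
            raise ValidationError(
                f"trap {self.trap_id} collection {self.collection_index}: "
                f"water_leftover must be >= 0"
            )


@dataclass(frozen=True)
class CageRecord:
    """One cage x sex observation for a single adulticide treatment."""

    treatment_id: str
    line_id: str
    role: CageRole
    distance_m: float
    sex: Sex
    n_initial: int
    n_dead_24h: int
    permethrin_ug_cm2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValidationError(
                f"{self.treatment_id}/{self.line_id}: n_initial must be positive"
            )
        if not 0 <= self.n_dead_24h <= self.n_initial:
            raise ValidationError(
                f"{self.treatment_id}/{self.line_id} ({self.sex.value}): "
                f"n_dead_24h={self.n_dead_24h} outside [0, {self.n_initial}]"
            )
        if self.distance_m < 0:
            raise ValidationError(
                f"{self.treatment_id}/{self.line_id}: distance_m must be >= 0"
            )
        if self.permethrin_ug_cm2 < 0:
            raise ValidationError(
                f"{self.treatment_id}/{self.line_id}: negative permethrin"
            )

    @property
    def n_alive_24h(self) -> int:
        return self.n_initial - self.n_dead_24h


@dataclass(frozen=True)
class ScheduleEntry:
    treatment_id: str
    date: _dt.date
    pre_collection_index: int
    post_collection_index: int

    def __post_init__(self) -> None:
        if self.pre_collection_index >= self.post_collection_index:
            raise ValidationError(
                f"{self.treatment_id}: pre_collection_index must precede "
                f"post_collection_index"
            )


@dataclass
class TreatmentSchedule:
    """Adulticide treatments anchored to the surrounding collections.

    ``pre_collection_index`` is the last collection completed before spraying
    (the day-6 collection of the treatment week) and ``post_collection_index``
    the first collection completed after it (the following day-3 collection).
    """

    entries: list[ScheduleEntry] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [e.date for e in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError("schedule dates must be strictly increasing")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, treatment_id: str) -> ScheduleEntry:
        for e in self.entries:
            if e.treatment_id == treatment_id:
                return e
        raise KeyError(f"unknown treatment {treatment_id!r}")


@dataclass(frozen=True)
class WeatherRecord:
    date: _dt.date
    tmax: float
    rainfall: float

    def __post_init__(self) -> None:
        if self.rainfall < 0:
            raise ValidationError(f"{self.date}: rainfall must be >= 0")


# ---------------------------------------------------------------------------
# Column layouts
# ---------------------------------------------------------------------------

TRAP_COLUMNS = (
    "trap_id",
    "site",
    "collection_index",
    "collection_date",
    "n_female",
    "n_male",
    "n_total",
    "water_leftover",
    "active",
)
CAGE_COLUMNS = (
    "treatment_id",
    "line_id",
    "role",
    "distance_m",
    "sex",
    "n_initial",
    "n_dead_24h",
    "permethrin_ug_cm2",
)
WEATHER_COLUMNS = ("date", "tmax", "rainfall")
SCHEDULE_COLUMNS = (
    "treatment_id",
    "date",
    "pre_collection_index",
    "post_collection_index",
)

def _float_repr(value) -> str:
    """Shortest round-trip decimal form (works for numpy scalars too)."""
    return repr(float(value))


#: Default worksheet names when reading XLSX workbooks.
TRAP_SHEET = "Wild mosquitos"
CAGE_SHEET = "Cage mosquitos"


def _load_table(
    path: str | Path,
    sheet: str | None,
    column_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path, sheet_name=sheet or 0)
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing columns {missing}; found "
            f"{list(frame.columns)}. Supply a column_map if the layout differs."
        )


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


def read_trap_table(
    path: str | Path,
    *,
    sheet: str | None = TRAP_SHEET,
    column_map: Mapping[str, str] | None = None,
) -> list[TrapRecord]:
    """Read sticky-trap records from a CSV/XLSX table.

    Inactive trap-collection pairs must be present with ``active`` false (or an
    ``active`` column absent, in which case every row is taken as active); they
    are flagged, never dropped.  Duplicate ``(trap_id, collection_index)`` pairs
    and count/invariant violations raise descriptive errors.
    """
    frame = _load_table(path, sheet, column_map)
    required = [c for c in TRAP_COLUMNS if c != "active"]
    _require_columns(frame, required, "trap")
    has_active = "active" in frame.columns

    records: list[TrapRecord] = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                TrapRecord(
                    trap_id=str(row["trap_id"]),
                    site=Site(str(row["site"]).strip().lower()),
                    collection_index=int(row["collection_index"]),
                    collection_date=_as_date(row["collection_date"]),
                    n_female=int(row["n_female"]),
                    n_male=int(row["n_male"]),
                    n_total=int(row["n_total"]),
                    water_leftover=float(row["water_leftover"]),
                    active=bool(row["active"]) if has_active else True,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"trap table row {idx}: {exc}") from exc

    seen: dict[tuple[str, int], int] = {}
    for i, rec in enumerate(records):
        key = (rec.trap_id, rec.collection_index)
        if key in seen:
            raise ValidationError(
                f"duplicate (trap_id, collection_index) = {key} at rows "
                f"{seen[key]} and {i}"
            )
        seen[key] = i

    by_trap: dict[str, list[TrapRecord]] = {}
    for rec in records:
        by_trap.setdefault(rec.trap_id, []).append(rec)
    for trap_id, recs in by_trap.items():
        recs = sorted(recs, key=lambda r: r.collection_index)
        for a, b in zip(recs, recs[1:]):
            if b.collection_date < a.collection_date:
                raise ValidationError(
                    f"trap {trap_id}: collection_date not increasing with "
                    f"collection_index ({a.collection_index} -> {b.collection_index})"
                )
    return records


def trap_frame(records: Iterable[TrapRecord]) -> pd.DataFrame:
    """Tabular view of trap records (enum fields as their string values)."""
    return pd.DataFrame(
        [
            {
                "trap_id": r.trap_id,
                "site": r.site.value,
                "collection_index": r.collection_index,
                "collection_date": r.collection_date.isoformat(),
                "n_female": r.n_female,
                "n_male": r.n_male,
                "n_total": r.n_total,
                "water_leftover": r.water_leftover,
                "active": r.active,
            }
            for r in records
        ]
    )


def write_trap_table(records: Iterable[TrapRecord], path: str | Path) -> None:
    trap_frame(records).to_csv(path, index=False, float_format=_float_repr)


def read_cage_table(
    path: str | Path,
    *,
    sheet: str | None = CAGE_SHEET,
    column_map: Mapping[str, str] | None = None,
) -> list[CageRecord]:
    """Read cage-experiment records (one row per cage x sex) from CSV/XLSX."""
    frame = _load_table(path, sheet, column_map)
    _require_columns(frame, CAGE_COLUMNS, "cage")
    records: list[CageRecord] = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                CageRecord(
                    treatment_id=str(row["treatment_id"]),
                    line_id=str(row["line_id"]),
                    role=CageRole(str(row["role"]).strip().lower()),
                    distance_m=float(row["distance_m"]),
                    sex=Sex(str(row["sex"]).strip().lower()),
                    n_initial=int(row["n_initial"]),
                    n_dead_24h=int(row["n_dead_24h"]),
                    permethrin_ug_cm2=float(row["permethrin_ug_cm2"]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"cage table row {idx}: {exc}") from exc
    return records


def cage_frame(records: Iterable[CageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatment_id": r.treatment_id,
                "line_id": r.line_id,
                "role": r.role.value,
                "distance_m": r.distance_m,
                "sex": r.sex.value,
                "n_initial": r.n_initial,
                "n_dead_24h": r.n_dead_24h,
                "permethrin_ug_cm2": r.permethrin_ug_cm2,
            }
            for r in records
        ]
    )


def write_cage_table(records: Iterable[CageRecord], path: str | Path) -> None:
    cage_frame(records).to_csv(path, index=False, float_format=_float_repr)


def read_weather_table(
    path: str | Path,
    *,
    sheet: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[WeatherRecord]:
    frame = _load_table(path, sheet, column_map)
    _require_columns(frame, WEATHER_COLUMNS, "weather")
    return [
        WeatherRecord(
            date=_as_date(row["date"]),
            tmax=float(row["tmax"]),
            rainfall=float(row["rainfall"]),
        )
        for _, row in frame.iterrows()
    ]


def write_weather_table(records: Iterable[WeatherRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"date": r.date.isoformat(), "tmax": r.tmax, "rainfall": r.rainfall}
            for r in records
        ]
    ).to_csv(path, index=False, float_format=_float_repr)


def read_schedule(
    path: str | Path,
    *,
    sheet: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TreatmentSchedule:
    frame = _load_table(path, sheet, column_map)
    _require_columns(frame, SCHEDULE_COLUMNS, "schedule")
    entries = [
        ScheduleEntry(
            treatment_id=str(row["treatment_id"]),
            date=_as_date(row["date"]),
            pre_collection_index=int(row["pre_collection_index"]),
            post_collection_index=int(row["post_collection_index"]),
        )
        for _, row in frame.iterrows()
    ]
    return TreatmentSchedule(entries=entries)


def write_schedule(schedule: TreatmentSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "treatment_id": e.treatment_id,
                "date": e.date.isoformat(),
                "pre_collection_index": e.pre_collection_index,
                "post_collection_index": e.post_collection_index,
            }
            for e in schedule
        ]
    ).to_csv(path, index=False, float_format=_float_repr)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def site_mean_series(
    records: Sequence[TrapRecord],
    variable: str = "count",
) -> dict[Site, pd.DataFrame]:
    """Per-site series of per-collection means over active traps.

    ``variable`` is ``"count"`` (total adults) or ``"water"`` (water leftover).
    Returns, per site, a frame indexed by ``collection_index`` (1..C, C = the
    largest index observed anywhere) with columns ``mean`` and ``n_traps``.
    Collections with zero active traps in a site carry ``mean = NaN`` and
    ``n_traps = 0`` — missingness is propagated explicitly, never filled.
    """
    if variable not in {"count", "water"}:
        raise ValueError("variable must be 'count' or 'water'")
    if not records:
        raise ValueError("no records supplied")
    col = "n_total" if variable == "count" else "water_leftover"
    frame = trap_frame(records)
    frame = frame[frame["active"]]
    n_collections = max(r.collection_index for r in records)
    index = pd.RangeIndex(1, n_collections + 1, name="collection_index")
    out: dict[Site, pd.DataFrame] = {}
    for site in Site:
        sub = frame[frame["site"] == site.value]
        grouped = sub.groupby("collection_index")[col].agg(["mean", "count"])
        grouped = grouped.rename(columns={"count": "n_traps"}).reindex(index)
        grouped["n_traps"] = grouped["n_traps"].fillna(0).astype(int)
        out[site] = grouped
    return out
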