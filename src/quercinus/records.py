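"""Domain records and validation for capture-mark-recapture tables.

The analysis operates on three tabular inputs: individual capture events,
fecal-sample residue areas, and daily minimum ambient temperatures. Records
are held in pandas DataFrames with a fixed column contract; the dataclasses
here define single-record views and the validation rules every row must
satisfy before entering a model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CaptureRecord",
    "FecalSample",
    "TemperatureSeries",
    "WinterSummary",
    "PeriodMap",
    "DIET_CATEGORIES",
    "SEXES",
    "AGE_CLASSES",
    "DEFAULT_PERIOD_MAP",
    "ValidationError",
    "RowValidationError",
    "TableFormatError",
]

#: Closed set of food-residue categories; "miscellaneous" holds unassigned area.
DIET_CATEGORIES = (
    "arthropods",
    "fruits",
    "seeds",
    "blossoms",
    "buds",
    "leaves",
    "moss",
    "miscellaneous",
)

SEXES = ("female", "male", "unknown")
AGE_CLASSES = ("juvenile", "adult")

# Plausibility bounds for field measurements (grams, millimetres).
BM_BOUNDS = (0.0, 300.0)
TL_BOUNDS = (5.0, 45.0)


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class RowValidationError(ValidationError):
    """One or more rows violated a record invariant.

    Attributes
    ----------
    errors : list of (row_index, message)
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.errors)
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}")


class TableFormatError(ValidationError):
    """The table as a whole is malformed (missing columns, duplicate dates...)."""


class PeriodMap:
    """Deterministic mapping from capture year to study period.

    Parameters
    ----------
    ranges
        Mapping of period label to an inclusive ``(first_year, last_year)``
        range. The default covers the two monitoring decades of the study
        design: 2003-2005 (period 1) and 2018-2021 (period 2).
    """

    def __init__(self, ranges: Mapping[int, tuple[int, int]] | None = None):
        self.ranges = dict(ranges) if ranges is not None else {
            1: (2003, 2005),
            2: (2018, 2021),
        }
        for period, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"period {period}: empty year range ({lo}, {hi})")

    def period_for_year(self, year: int) -> int:
        for period, (lo, hi) in self.ranges.items():
            if lo <= year <= hi:
                return period
        raise ValidationError(f"year {year} is outside every configured period range")

    def __eq__(self, other):  # pragma: no cover - convenience
        return isinstance(other, PeriodMap) and self.ranges == other.ranges


DEFAULT_PERIOD_MAP = PeriodMap()


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event of a marked individual."""

    individual_id: str
    capture_date: dt.date
    site: str
    sex: str
    age_class: str
    body_mass: float
    tibia_length: float | None = None
    period: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.individual_id:
            problems.append("empty individual_id")
        if not self.site:
            problems.append("empty site")
        if self.sex not in SEXES:
            problems.append(f"sex {self.sex!r} not in {SEXES}")
        if self.age_class not in AGE_CLASSES:
            problems.append(f"age_class {self.age_class!r} not in {AGE_CLASSES}")
        if not (BM_BOUNDS[0] < self.body_mass < BM_BOUNDS[1]):
            problems.append(
                f"body_mass {self.body_mass} g outside ({BM_BOUNDS[0]}, {BM_BOUNDS[1]})"
            )
        if self.tibia_length is not None and not (
            TL_BOUNDS[0] < self.tibia_length < TL_BOUNDS[1]
        ):
            problems.append(
                f"tibia_length {self.tibia_length} mm outside {TL_BOUNDS}"
            )
        return problems


@dataclass(frozen=True)
class FecalSample:
    """Residue areas (mm^2) of one fecal sample, by food category."""

    individual_id: str
    sample_date: dt.date
    age_class: str
    areas: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if self.age_class not in AGE_CLASSES:
            problems.append(f"age_class {self.age_class!r} not in {AGE_CLASSES}")
        unknown = set(self.areas) - set(DIET_CATEGORIES)
        if unknown:
            problems.append(f"unknown categories {sorted(unknown)}")
        if any(v < 0 for v in self.areas.values()):
            problems.append("negative residue area")
        if not any(v > 0 for v in self.areas.values()):
            problems.append("all residue areas are zero")
        return problems

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily minimum ambient temperature (deg C), strictly increasing dates."""

    dates: tuple[dt.date, ...]
    tmin_c: tuple[float, ...]

    def __post_init__(self):
        if len(self.dates) != len(self.tmin_c):
            raise ValueError("dates and temperatures differ in length")
        for a, b in zip(self.dates, self.dates[1:]):
            if a >= b:
                raise TableFormatError(f"dates not strictly increasing at {b}")

    def __len__(self) -> int:
        return len(self.dates)

    def between(self, start: dt.date, end: dt.date) -> np.ndarray:
        """Temperatures for dates in the inclusive window [start, end]."""
        return np.array(
            [t for d, t in zip(self.dates, self.tmin_c) if start <= d <= end],
            dtype=float,
        )


@dataclass(frozen=True)
class WinterSummary:
    """Median daily-minimum temperature over one hibernation window.

    The window runs from 1 October of ``winter_label`` through 30 April of
    the following year; ``t_aminhib_c`` is the exact sample median of the
    daily minima inside the window.
    """

    winter_label: int
    t_aminhib_c: float
    n_days: int
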