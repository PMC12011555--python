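"""Readers and writers for the three tabular inputs, plus the winter
temperature summary.

All files are plain CSV with ISO-8601 dates. Captures carry the header
``individual_id,capture_date,site,sex,age_class,body_mass_g,tibia_length_mm``;
temperatures use ``date,tmin_c`` (the shape of a DWD daily-minimum export,
without station metadata); fecal tables carry one ``<category>_mm2`` column
per food category.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    AGE_CLASSES,
    DIET_CATEGORIES,
    DEFAULT_PERIOD_MAP,
    CaptureRecord,
    FecalSample,
    PeriodMap,
    RowValidationError,
    TableFormatError,
    TemperatureSeries,
    ValidationError,
    WinterSummary,
)

__all__ = [
    "CAPTURE_COLUMNS",
    "read_captures",
    "write_captures",
    "captures_to_frame",
    "read_daily_min_temperature",
    "write_daily_min_temperature",
    "compute_t_aminhib",
    "read_fecal_samples",
    "write_fecal_samples",
    "hibernation_window",
]

CAPTURE_COLUMNS = [
    "individual_id",
    "capture_date",
    "site",
    "sex",
    "age_class",
    "body_mass_g",
    "tibia_length_mm",
]

TEMPERATURE_COLUMNS = ["date", "tmin_c"]


def _parse_date(value, row: int, errors: list) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        errors.append((row, f"unparseable date {value!r}"))
        return None


def read_captures(
    path: str | Path, period_map: PeriodMap | None = None
) -> list[CaptureRecord]:
    """Read and validate a capture table.

    Every row becomes a :class:`CaptureRecord` with its study period assigned
    from the capture year via ``period_map``. Rows violating any record
    invariant are rejected collectively with row-indexed diagnostics.
    """
    period_map = period_map or DEFAULT_PERIOD_MAP
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {missing}")

    records: list[CaptureRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        date = _parse_date(row["capture_date"], i, errors)
        if date is None:
            continue
        try:
            bm = float(row["body_mass_g"])
        except ValueError:
            errors.append((i, f"non-numeric body mass {row['body_mass_g']!r}"))
            continue
        tl_raw = str(row["tibia_length_mm"]).strip()
        tl = None
        if tl_raw not in ("", "NA", "nan"):
            try:
                tl = float(tl_raw)
            except ValueError:
                errors.append((i, f"non-numeric tibia length {tl_raw!r}"))
                continue
        try:
            period = period_map.period_for_year(date.year)
        except ValidationError as exc:
            errors.append((i, str(exc)))
            continue
        rec = CaptureRecord(
            individual_id=str(row["individual_id"]).strip(),
            capture_date=date,
            site=str(row["site"]).strip(),
            sex=str(row["sex"]).strip(),
            age_class=str(row["age_class"]).strip(),
            body_mass=bm,
            tibia_length=tl,
            period=period,
        )
        problems = rec.validate()
        if problems:
            errors.extend((i, p) for p in problems)
        else:
            records.append(rec)
    if errors:
        raise RowValidationError(errors)
    return records


def captures_to_frame(records: list[CaptureRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a capture collection (analysis container)."""
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "capture_date": [r.capture_date for r in records],
            "site": [r.site for r in records],
            "sex": [r.sex for r in records],
            "age_class": [r.age_class for r in records],
            "body_mass": [r.body_mass for r in records],
            "tibia_length": [
                np.nan if r.tibia_length is None else r.tibia_length for r in records
            ],
            "period": [r.period for r in records],
        }
    )


def write_captures(records: list[CaptureRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "capture_date": [r.capture_date.isoformat() for r in records],
            "site": [r.site for r in records],
            "sex": [r.sex for r in records],
            "age_class": [r.age_class for r in records],
            "body_mass_g": [_fmt_num(r.body_mass) for r in records],
            "tibia_length_mm": [
                "" if r.tibia_length is None else _fmt_num(r.tibia_length)
                for r in records
            ],
        }
    )
    df.to_csv(path, index=False)


def _fmt_num(x: float) -> str:
    return repr(float(x))


def read_daily_min_temperature(path: str | Path) -> TemperatureSeries:
    """Read a daily-minimum temperature CSV into an ordered series.

    Input rows may be unsorted; the returned series is sorted ascending.
    Duplicate dates are a format error; non-numeric temperatures are row
    errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TEMPERATURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {missing}")
    errors: list[tuple[int, str]] = []
    pairs: list[tuple[dt.date, float]] = []
    for i, row in df.iterrows():
        date = _parse_date(row["date"], i, errors)
        if date is None:
            continue
        try:
            pairs.append((date, float(row["tmin_c"])))
        except ValueError:
            errors.append((i, f"non-numeric temperature {row['tmin_c']!r}"))
    if errors:
        raise RowValidationError(errors)
    pairs.sort(key=lambda p: p[0])
    for (d1, _), (d2, _) in zip(pairs, pairs[1:]):
        if d1 == d2:
            raise TableFormatError(f"duplicate date {d1.isoformat()}")
    return TemperatureSeries(
        dates=tuple(p[0] for p in pairs), tmin_c=tuple(p[1] for p in pairs)
    )


def write_daily_min_temperature(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "date": [d.isoformat() for d in series.dates],
            "tmin_c": [repr(float(t)) for t in series.tmin_c],
        }
    ).to_csv(path, index=False)


def hibernation_window(winter_start_year: int) -> tuple[dt.date, dt.date]:
    """The fixed hibernation window: 1 Oct of the start year - 30 Apr next."""
    return (
        dt.date(winter_start_year, 10, 1),
        dt.date(winter_start_year + 1, 4, 30),
    )


def compute_t_aminhib(
    series: TemperatureSeries, winter_start_year: int
) -> WinterSummary:
    """Median of the daily minimum temperatures over one hibernation window.

    Days outside 1 October - 30 April never contribute; the median is the
    exact sample median (mean of the two central order statistics for even
    counts).
    """
    start, end = hibernation_window(winter_start_year)
    values = series.between(start, end)
    if values.size == 0:
        raise ValidationError(
            f"no temperature data inside the window {start} - {end}"
        )
    return WinterSummary(
        winter_label=winter_start_year,
        t_aminhib_c=float(np.median(values)),
        n_days=int(values.size),
    )


def _fecal_area_columns() -> list[str]:
    return [f"{c}_mm2" for c in DIET_CATEGORIES]


def read_fecal_samples(path: str | Path) -> list[FecalSample]:
    """Read and validate a fecal residue-area table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    base = ["individual_id", "sample_date", "age_class"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {missing}")
    area_cols = [c for c in _fecal_area_columns() if c in df.columns]
    if not area_cols:
        raise TableFormatError("no <category>_mm2 area columns found")

    samples: list[FecalSample] = []
    errors: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        date = _parse_date(row["sample_date"], i, errors)
        if date is None:
            continue
        areas = {}
        bad = False
        for col in area_cols:
            raw = str(row[col]).strip()
            try:
                areas[col[: -len("_mm2")]] = float(raw) if raw else 0.0
            except ValueError:
                errors.append((i, f"non-numeric area {raw!r} in {col}"))
                bad = True
        if bad:
            continue
        sample = FecalSample(
            individual_id=str(row["individual_id"]).strip(),
            sample_date=date,
            age_class=str(row["age_class"]).strip(),
            areas=areas,
        )
        problems = sample.validate()
        if problems:
            errors.extend((i, p) for p in problems)
        else:
            samples.append(sample)
    if errors:
        raise RowValidationError(errors)
    return samples


def write_fecal_samples(samples: list[FecalSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {
            "individual_id": s.individual_id,
            "sample_date": s.sample_date.isoformat(),
            "age_class": s.age_class,
        }
        for cat in DIET_CATEGORIES:
            row[f"{cat}_mm2"] = repr(float(s.areas.get(cat, 0.0)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
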