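"""Field-scale NDVI series I/O: containers, readers/writers, and filters.

The on-disk layout is two long-format CSV files: a *series* table with one
row per (field, date) observation — columns ``field_id, date, ndvi`` — and a
*metadata* table keyed by ``field_id`` with columns
``field_id, crop, irrigation, county, area, survey_year``. Dates are
ISO-8601 unless a different format is declared in :class:`SeriesSchema`.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ("field_id", "date", "ndvi")
META_COLUMNS = ("field_id", "crop", "irrigation", "county", "area", "survey_year")


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


class DegenerateInputError(ValueError):
    """Input is mathematically unusable (e.g. nir + red = 0)."""


def compute_ndvi(nir: float, red: float) -> float:
    """Normalized Difference Vegetation Index, (NIR − Red) / (NIR + Red).

    Both reflectances must be nonnegative; the result lies in [−1, 1].

    Raises
    ------
    DegenerateInputError
        If ``nir + red == 0`` (no signal in either band).
    """
    nir = float(nir)
    red = float(red)
    if nir < 0 or red < 0:
        raise ValueError(f"reflectances must be nonnegative, got nir={nir}, red={red}")
    denom = nir + red
    if denom == 0:
        raise DegenerateInputError("nir + red = 0: NDVI undefined")
    return (nir - red) / denom


@dataclass(frozen=True)
class Observation:
    """A single dated NDVI value for one field."""

    date: _dt.date
    ndvi: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(f"ndvi {self.ndvi} outside [-1, 1]")

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class FieldMeta:
    """Per-field survey attributes (crop, irrigation, county, acreage)."""

    field_id: str
    crop: str = "unknown"
    irrigation: str = "unknown"
    county: str = "unknown"
    area: float = 1.0
    survey_year: int = 0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"area must be > 0, got {self.area}")


@dataclass(frozen=True)
class FieldSeries:
    """One field-year of dated NDVI observations, strictly increasing in date."""

    meta: FieldMeta
    year: int
    observations: tuple[Observation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        dates = [o.date for o in self.observations]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("observations must be strictly increasing in date")

    @property
    def doys(self) -> np.ndarray:
        return np.array([o.doy for o in self.observations], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([o.ndvi for o in self.observations], dtype=float)

    def with_values(self, values: Sequence[float]) -> "FieldSeries":
        """Copy of this series with the NDVI values replaced, dates kept."""
        if len(values) != len(self.observations):
            raise ValueError("length mismatch")
        obs = tuple(
            Observation(o.date, float(v)) for o, v in zip(self.observations, values)
        )
        return replace(self, observations=obs)


@dataclass(frozen=True)
class SeriesSchema:
    """Column names and date format for the long-format series CSV."""

    field_id: str = "field_id"
    date: str = "date"
    ndvi: str = "ndvi"
    date_format: str = "%Y-%m-%d"


def _parse_meta_table(path: str | Path) -> dict[str, FieldMeta]:
    df = pd.read_csv(path, dtype={"field_id": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"metadata file {path} missing columns: {sorted(missing)}")
    out: dict[str, FieldMeta] = {}
    for row in df.itertuples(index=False):
        fid = str(row.field_id)
        if fid in out:
            raise SchemaError(f"duplicate field_id {fid!r} in metadata")
        out[fid] = FieldMeta(
            field_id=fid,
            crop=str(row.crop),
            irrigation=str(row.irrigation),
            county=str(row.county),
            area=float(row.area),
            survey_year=int(row.survey_year),
        )
    return out


def read_series_table(
    path: str | Path,
    schema: SeriesSchema | None = None,
    meta: Mapping[str, FieldMeta] | str | Path | None = None,
) -> list[FieldSeries]:
    """Read a long-format series CSV into one :class:`FieldSeries` per field-year.

    Rows are grouped by (field_id, calendar year of date) and sorted by date.
    Duplicate (field, date) rows are collapsed to their mean with a warning.
    ``meta`` may be a metadata CSV path or a prebuilt mapping; fields without
    metadata get a default :class:`FieldMeta`.
    """
    schema = schema or SeriesSchema()
    df = pd.read_csv(path, dtype={schema.field_id: str})
    required = {schema.field_id, schema.date, schema.ndvi}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"series file {path} missing columns: {sorted(missing)}")
    if meta is not None and not isinstance(meta, Mapping):
        meta = _parse_meta_table(meta)
    meta = meta or {}

    if df.empty:
        return []

    try:
        df[schema.date] = pd.to_datetime(df[schema.date], format=schema.date_format)
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_datetime(df[schema.date], format=schema.date_format,
                                errors="coerce").isna()]
        raise SchemaError(
            f"unparseable dates in rows {list(bad.index[:10])}: {exc}"
        ) from exc
    bad_vals = df[~np.isfinite(pd.to_numeric(df[schema.ndvi], errors="coerce"))]
    if len(bad_vals):
        raise SchemaError(f"unparseable ndvi values in rows {list(bad_vals.index[:10])}")

    dupes = df.duplicated(subset=[schema.field_id, schema.date], keep=False)
    if dupes.any():
        logger.warning(
            "collapsing %d duplicate (field, date) rows to their mean",
            int(dupes.sum()),
        )
        df = (
            df.groupby([schema.field_id, schema.date], as_index=False)[schema.ndvi]
            .mean()
        )

    out: list[FieldSeries] = []
    df["_year"] = df[schema.date].dt.year
    for (fid, year), grp in df.groupby([schema.field_id, "_year"], sort=True):
        grp = grp.sort_values(schema.date)
        obs = tuple(
            Observation(ts.date(), float(v))
            for ts, v in zip(grp[schema.date], grp[schema.ndvi])
        )
        fmeta = meta.get(str(fid), FieldMeta(field_id=str(fid)))
        out.append(FieldSeries(meta=fmeta, year=int(year), observations=obs))
    return out


def write_series_table(collection: Iterable[FieldSeries], path: str | Path) -> None:
    """Write series to a long-format CSV (round-trips through read to 1e-9)."""
    rows = [
        (s.meta.field_id, o.date.isoformat(), o.ndvi)
        for s in collection
        for o in s.observations
    ]
    df = pd.DataFrame(rows, columns=list(SERIES_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def write_meta_table(collection: Iterable[FieldSeries], path: str | Path) -> None:
    """Write one metadata row per distinct field."""
    seen: dict[str, FieldMeta] = {}
    for s in collection:
        seen.setdefault(s.meta.field_id, s.meta)
    df = pd.DataFrame(
        [
            (m.field_id, m.crop, m.irrigation, m.county, m.area, m.survey_year)
            for m in seen.values()
        ],
        columns=list(META_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.12g")


def filter_fields(
    dataset: Sequence[FieldSeries], min_area: float = 10.0
) -> list[FieldSeries]:
    """Drop fields smaller than ``min_area`` acres (strict <; 10-acre fields stay).

    Small fields average too few 30 m pixels for a stable field-scale NDVI,
    so they are removed before any classification. Logs the count and total
    acreage removed.
    """
    kept = [s for s in dataset if s.meta.area >= min_area]
    removed = [s for s in dataset if s.meta.area < min_area]
    if removed:
        logger.warning(
            "filter_fields: removed %d fields (%.1f acres) below %g acres",
            len(removed),
            sum(s.meta.area for s in removed),
            min_area,
        )
    if not kept:
        logger.warning("filter_fields: no fields remain")
    return kept
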