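"""CSV reading/writing of daily panels, metadata, and station–region matching.

Formats are deliberately plain: comma-separated UTF-8 with a mandatory
header, ISO-8601 dates, ``.`` decimal point, and an *empty* value field for
a missing day (a literal ``0`` is a reported zero — the distinction carries
through the whole analysis).

Series CSV columns: ``id,date,value`` plus an optional ``replicate`` column
for search data (one block of rows per download replicate).
Metadata CSV columns: ``id,latitude,longitude[,tv_homes]``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    POLLEN,
    SEARCH,
    DailySeries,
    RegionYear,
    StationYear,
    year_length,
)

__all__ = [
    "SiteMetadata",
    "read_metadata_csv",
    "read_series_csv",
    "write_series_csv",
    "write_metadata_csv",
    "match_station_to_region",
    "MatchResult",
]


@dataclass(frozen=True)
class SiteMetadata:
    site_id: str
    latitude: float
    longitude: float
    tv_homes: float | None = None


def read_metadata_csv(path) -> dict[str, SiteMetadata]:
    """Load site metadata keyed by id (columns id, latitude, longitude[, tv_homes])."""
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    required = {"id", "latitude", "longitude"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
    out: dict[str, SiteMetadata] = {}
    for row in frame.itertuples(index=False):
        tv = getattr(row, "tv_homes", None)
        out[row.id] = SiteMetadata(
            site_id=row.id,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            tv_homes=None if tv is None or pd.isna(tv) else float(tv),
        )
    return out


def _parse_dates(raw: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: malformed date {raw.iloc[row]!r} at data row {row + 1}"
        )
    return parsed


def read_series_csv(
    path,
    kind: str,
    metadata: dict[str, SiteMetadata] | None = None,
) -> list[StationYear] | list[RegionYear]:
    """Read a daily-series CSV into station-years or region-years.

    One object is produced per (id, calendar year).  For search data, rows
    are grouped by the ``replicate`` column (absent means a single
    replicate).  Duplicate (id, date, replicate) rows are an error, as are
    negative values and search values above 100 — each reported with its
    row number.
    """
    frame = pd.read_csv(
        path, dtype={"id": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    required = {"id", "date", "value"}
    if missing := required - set(frame.columns):
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    frame = frame.copy()
    frame["date"] = _parse_dates(frame["date"].astype(str), path)
    values = pd.to_numeric(frame["value"], errors="raise")
    arr = values.to_numpy(dtype=float)
    if np.any(arr < 0):
        row = int(np.flatnonzero(arr < 0)[0])
        raise ValueError(f"{path}: negative value {arr[row]} at data row {row + 1}")
    if kind == SEARCH and np.any(arr > 100):
        row = int(np.flatnonzero(arr > 100)[0])
        raise ValueError(f"{path}: search value {arr[row]} > 100 at data row {row + 1}")
    frame["value"] = values
    if "replicate" not in frame.columns:
        frame["replicate"] = 0
    dup = frame.duplicated(subset=["id", "date", "replicate"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate (id, date, replicate) at data row {row + 1}"
        )
    frame["year"] = frame["date"].dt.year
    frame["doy"] = frame["date"].dt.dayofyear

    out: list = []
    for (site_id, year), group in frame.groupby(["id", "year"], sort=True):
        year = int(year)
        meta = (metadata or {}).get(site_id)
        if kind == POLLEN:
            series = _series_from_rows(group, year, POLLEN)
            out.append(
                StationYear(
                    station_id=site_id,
                    latitude=meta.latitude if meta else 0.0,
                    longitude=meta.longitude if meta else 0.0,
                    series=series,
                )
            )
        else:
            replicates = [
                _series_from_rows(rep_rows, year, SEARCH)
                for _, rep_rows in group.groupby("replicate", sort=True)
            ]
            out.append(
                RegionYear(
                    dma_id=site_id,
                    latitude=meta.latitude if meta else 0.0,
                    longitude=meta.longitude if meta else 0.0,
                    tv_homes=(meta.tv_homes if meta and meta.tv_homes else 1.0),
                    replicates=tuple(replicates),
                )
            )
    return out


def _series_from_rows(rows: pd.DataFrame, year: int, kind: str) -> DailySeries:
    values = np.full(year_length(year), np.nan)
    doy = rows["doy"].to_numpy(dtype=int)
    values[doy - 1] = rows["value"].to_numpy(dtype=float)
    return DailySeries(year=year, values=values, kind=kind)


def _series_rows(site_id: str, series: DailySeries, replicate: int | None):
    base = _dt.date(series.year, 1, 1)
    for day in series.days:
        value = series.values[day - 1]
        row = {
            "id": site_id,
            "date": (base + _dt.timedelta(days=int(day) - 1)).isoformat(),
            "value": "" if np.isnan(value) else value,
        }
        if replicate is not None:
            row["replicate"] = replicate
        yield row


def write_series_csv(items, path) -> None:
    """Write station-years or region-years back to the series CSV dialect.

    Region-years emit one row block per replicate; missing days are written
    with an empty value field so a read round-trips them exactly.
    """
    rows: list[dict] = []
    for item in items:
        if isinstance(item, StationYear):
            rows.extend(_series_rows(item.station_id, item.series, None))
        elif isinstance(item, RegionYear):
            for r, rep in enumerate(item.replicates):
                rows.extend(_series_rows(item.dma_id, rep, r))
        else:
            raise TypeError(f"cannot write {type(item).__name__}")
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metadata_csv(items, path) -> None:
    rows = []
    for item in items:
        if isinstance(item, StationYear):
            rows.append(
                {"id": item.station_id, "latitude": item.latitude,
                 "longitude": item.longitude}
            )
        else:
            rows.append(
                {"id": item.dma_id, "latitude": item.latitude,
                 "longitude": item.longitude, "tv_homes": item.tv_homes}
            )
    frame = pd.DataFrame(rows).drop_duplicates(subset="id")
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class MatchResult:
    pairs: list[tuple[str, str]]          # (station_id, dma_id)
    unmatched_stations: list[str]


def match_station_to_region(
    stations, regions, max_delta_deg: float = 0.3
) -> MatchResult:
    """Pair each station with the closest search region on a per-axis rule.

    A region qualifies when *both* |Δlatitude| and |Δlongitude| are at most
    ``max_delta_deg`` (default 0.3°); among qualifiers the one minimising the
    Chebyshev distance max(|Δlat|, |Δlon|) wins, ties broken by region id
    for determinism.  Stations with no qualifying region are reported, not
    errored — sparse coverage is an expected outcome.
    """
    region_list = list(regions)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for station in stations:
        best: tuple[float, str] | None = None
        for region in region_list:
            dlat = abs(station.latitude - region.latitude)
            dlon = abs(station.longitude - region.longitude)
            if dlat <= max_delta_deg and dlon <= max_delta_deg:
                key = (max(dlat, dlon), region.dma_id)
                if best is None or key < best:
                    best = key
        if best is None:
            unmatched.append(station.station_id)
        else:
            pairs.append((station.station_id, best[1]))
    return MatchResult(pairs=pairs, unmatched_stations=unmatched)
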