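"""Daily time-series containers for one calendar year of surveillance data.

The analysis unit throughout the package is the *site-year*: one calendar
year of daily values from one pollen-counting station (grains/m³) or one
search-market region (relative search volume, 0–100).  Values are stored in
a dense day-of-year indexed array with NaN as the explicit missing marker;
a reported zero and a missing day are distinct states, because search feeds
censor low absolute volumes to 0 while pollen stations simply skip days.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

POLLEN = "pollen_grains_per_m3"
SEARCH = "search_volume_0_100"
# Output of log/smoothing transforms: unit-scale range checks no longer apply.
TRANSFORMED = "transformed"

__all__ = [
    "POLLEN",
    "SEARCH",
    "TRANSFORMED",
    "DailySeries",
    "StationYear",
    "RegionYear",
    "year_length",
    "jan_jun_window",
]


def year_length(year: int) -> int:
    """Number of days in ``year`` (365, or 366 for leap years)."""
    return 366 if calendar.isleap(year) else 365


def jan_jun_window(year: int) -> tuple[int, int]:
    """Inclusive day-of-year range covering January 1 – June 30."""
    return (1, _dt.date(year, 6, 30).timetuple().tm_yday)


def weekend_days(year: int) -> np.ndarray:
    """Day-of-year numbers of all Saturdays and Sundays in ``year``."""
    days = np.arange(1, year_length(year) + 1)
    jan1 = _dt.date(year, 1, 1).weekday()  # Monday == 0
    weekday = (jan1 + days - 1) % 7
    return days[weekday >= 5]


@dataclass(frozen=True)
class DailySeries:
    """One calendar year of dated daily values with explicit missingness.

    Parameters
    ----------
    year
        Calendar year the series covers (drives leap-day and weekday logic).
    values
        Dense array of length 365/366; index ``i`` holds day-of-year
        ``i + 1``.  NaN marks a missing (unmeasured or unquantified) day.
    kind
        Either :data:`POLLEN` or :data:`SEARCH`.
    window
        Inclusive day-of-year range this series covers; days outside it are
        not part of the series at all (as opposed to missing).  Defaults to
        the full year.
    flags
        Free-form provenance flags, e.g. ``"all_censored"`` for a search
        replicate whose every latent value fell below the display threshold.
    """

    year: int
    values: np.ndarray
    kind: str = POLLEN
    window: tuple[int, int] = None  # type: ignore[assignment]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = year_length(self.year)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (n,):
            raise ValueError(
                f"values must have length {n} for year {self.year}, "
                f"got shape {values.shape}"
            )
        if self.kind not in (POLLEN, SEARCH, TRANSFORMED):
            raise ValueError(f"unknown series kind: {self.kind!r}")
        window = self.window if self.window is not None else (1, n)
        lo, hi = int(window[0]), int(window[1])
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"window {window} outside 1..{n}")
        # NaN compares False, so these reductions ignore missing days.
        if self.kind == POLLEN and bool(np.any(values < 0)):
            raise ValueError("pollen values must be non-negative")
        if self.kind == SEARCH and bool(np.any((values < 0) | (values > 100))):
            raise ValueError("search values must lie in [0, 100]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "window", (lo, hi))

    # -- basic accessors -------------------------------------------------

    @property
    def days(self) -> np.ndarray:
        """Day-of-year numbers covered by the window (inclusive)."""
        return np.arange(self.window[0], self.window[1] + 1)

    @property
    def window_values(self) -> np.ndarray:
        """Values at the window days (NaN = missing)."""
        return self.values[self.window[0] - 1 : self.window[1]]

    @property
    def n_days(self) -> int:
        return self.window[1] - self.window[0] + 1

    @property
    def observed_mask(self) -> np.ndarray:
        """Full-year boolean mask: inside the window and non-missing."""
        mask = ~np.isnan(self.values)
        mask[: self.window[0] - 1] = False
        mask[self.window[1] :] = False
        return mask

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def value_on(self, day: int) -> float:
        """Value on a 1-based day-of-year (NaN if missing or out of window)."""
        if not (self.window[0] <= day <= self.window[1]):
            return float("nan")
        return float(self.values[day - 1])

    # -- construction helpers --------------------------------------------

    def with_values(self, values: np.ndarray, **overrides) -> "DailySeries":
        """Copy of this series with new values (and optional field overrides)."""
        kwargs = dict(
            year=self.year,
            values=values,
            kind=self.kind,
            window=self.window,
            flags=self.flags,
        )
        kwargs.update(overrides)
        return DailySeries(**kwargs)

    @classmethod
    def from_mapping(
        cls, year: int, day_values: Iterable[tuple[int, float]], kind: str = POLLEN
    ) -> "DailySeries":
        """Build a series from (day-of-year, value) pairs; other days missing."""
        values = np.full(year_length(year), np.nan)
        for day, value in day_values:
            values[int(day) - 1] = value
        return cls(year=year, values=values, kind=kind)


@dataclass(frozen=True)
class StationYear:
    """One pollen counting station's data for one calendar year."""

    station_id: str
    latitude: float
    longitude: float
    series: DailySeries

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(
                f"station {self.station_id}: coordinates out of range "
                f"({self.latitude}, {self.longitude})"
            )
        if self.series.kind != POLLEN:
            raise ValueError("StationYear series must be pollen-kind")

    @property
    def site_year_id(self) -> str:
        return f"{self.station_id}:{self.series.year}"


def average_replicates(replicates: list[DailySeries]) -> DailySeries:
    """Day-wise arithmetic mean across download replicates.

    Censored zeros enter the mean as zeros; a day missing in every replicate
    stays missing in the average.
    """
    if not replicates:
        raise ValueError("no replicates to average")
    stacked = np.vstack([r.values for r in replicates])
    all_nan = np.all(np.isnan(stacked), axis=0)
    mean = np.nanmean(np.where(all_nan[None, :], 0.0, stacked), axis=0)
    mean = np.where(all_nan, np.nan, mean)
    first = replicates[0]
    flags = tuple(sorted({f for r in replicates for f in r.flags}))
    return first.with_values(mean, flags=flags)


@dataclass(frozen=True)
class RegionYear:
    """One search-market region's data for one calendar year.

    ``tv_homes`` is the Nielsen count of television-owning households in the
    market, a proxy for population size and media use; it predicts how often
    the search feed censors low-volume days to zero.
    """

    dma_id: str
    latitude: float
    longitude: float
    tv_homes: float
    replicates: tuple[DailySeries, ...]
    averaged: DailySeries = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(
                f"region {self.dma_id}: coordinates out of range "
                f"({self.latitude}, {self.longitude})"
            )
        if not self.tv_homes > 0:
            raise ValueError(f"region {self.dma_id}: tv_homes must be positive")
        replicates = tuple(self.replicates)
        if not replicates:
            raise ValueError(f"region {self.dma_id}: needs at least one replicate")
        object.__setattr__(self, "replicates", replicates)
        if self.averaged is None:
            object.__setattr__(self, "averaged", average_replicates(list(replicates)))

    @property
    def site_year_id(self) -> str:
        return f"{self.dma_id}:{self.averaged.year}"


def _replace(obj, **changes):
    return dataclasses.replace(obj, **changes)
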