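"""Station-year data-quality metrics and inclusion screening.

Counting stations are asked to sample at least three times a week, but
compliance varies enormously: missingness clusters at year edges and on
weekends, and multi-day gaps near the first "high" pollen day corrupt
exactly the window the early-season analysis cares about.  A station-year
is excluded when

* more than 60% of the calendar year's days are missing (strict), or
* a run of more than 4 consecutive missing days (strict) intersects the
  ±10-day neighbourhood of the first day reaching the "high" concentration
  threshold (200 grains/m³), or
* it has no data at all inside the analysis window.

Boundary cases follow the strict wording: exactly 60% missing and an
exactly 4-day gap both pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SEARCH, DailySeries

__all__ = [
    "QualityThresholds",
    "QualityReport",
    "percent_missing",
    "longest_gap",
    "missing_runs",
    "first_high_day",
    "first_data_day",
    "apply_inclusion",
]

REASON_NO_DATA = "no_data_in_window"
REASON_MISSINGNESS = "missingness"
REASON_GAP_NEAR_HIGH = "gap_near_first_high"


@dataclass(frozen=True)
class QualityThresholds:
    """Inclusion-rule parameters (defaults are the study's operating values)."""

    max_pct_missing: float = 60.0      # strict: excluded when pct > this
    max_gap_near_high: int = 4         # strict: excluded when run length > this
    high_threshold: float = 200.0      # grains/m³ defining a "high" pollen day
    high_window_halfwidth: int = 10    # days either side of the first high day
    gt_sparse_floor: int | None = None  # optional min non-missing days (search)

    def __post_init__(self) -> None:
        for name in ("max_pct_missing", "max_gap_near_high", "high_threshold",
                     "high_window_halfwidth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class QualityReport:
    site_year_id: str
    pct_missing_days: float
    longest_gap_days: int
    first_data_day: int | None
    first_high_day: int | None
    gap_near_first_high_days: int
    included: bool
    exclusion_reasons: tuple[str, ...] = ()


def _window_or_default(series: DailySeries, window) -> tuple[int, int]:
    if window is None:
        return series.window
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ValueError(f"empty window {window}")
    return (max(lo, series.window[0]), min(hi, series.window[1]))


def _missing_in_window(
    series: DailySeries, window, censored_zero_as_missing: bool
) -> np.ndarray:
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    values = series.values[lo - 1 : hi]
    missing = np.isnan(values)
    if censored_zero_as_missing and series.kind == SEARCH:
        missing = missing | (values == 0)
    return missing


def percent_missing(
    series: DailySeries,
    window=None,
    censored_zero_as_missing: bool = False,
) -> float:
    """Percentage of days in ``window`` with no usable value.

    For search series, ``censored_zero_as_missing=True`` also counts reported
    zeros — volumes the feed refused to quantify — as missing, which is the
    convention for the search-side missingness covariate.
    """
    lo, hi = _window_or_default(series, window)
    missing = _missing_in_window(series, (lo, hi), censored_zero_as_missing)
    return 100.0 * float(missing.sum()) / missing.size


def missing_runs(
    series: DailySeries, window=None, censored_zero_as_missing: bool = False
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive missing days, as inclusive (start, end) days."""
    lo, hi = _window_or_default(series, window)
    missing = _missing_in_window(series, (lo, hi), censored_zero_as_missing)
    runs: list[tuple[int, int]] = []
    start = None
    for offset, is_missing in enumerate(missing):
        if is_missing and start is None:
            start = offset
        elif not is_missing and start is not None:
            runs.append((lo + start, lo + offset - 1))
            start = None
    if start is not None:
        runs.append((lo + start, lo + missing.size - 1))
    return runs


def longest_gap(series: DailySeries, window=None) -> int:
    """Length of the longest run of consecutive missing days inside ``window``.

    Runs extending beyond the window count only their in-window days.
    """
    runs = missing_runs(series, window)
    return max((end - start + 1 for start, end in runs), default=0)


def first_data_day(series: DailySeries, window=None) -> int | None:
    """Day-of-year of the first non-missing value, or None."""
    lo, hi = _window_or_default(series, window)
    values = series.values[lo - 1 : hi]
    idx = np.flatnonzero(~np.isnan(values))
    return int(lo + idx[0]) if idx.size else None


def first_high_day(
    series: DailySeries, high_threshold: float = 200.0, window=None
) -> int | None:
    """First day whose (non-missing) value reaches ``high_threshold``, or None."""
    lo, hi = _window_or_default(series, window)
    values = series.values[lo - 1 : hi]
    with np.errstate(invalid="ignore"):
        idx = np.flatnonzero(values >= high_threshold)
    return int(lo + idx[0]) if idx.size else None


def apply_inclusion(
    series: DailySeries,
    thresholds: QualityThresholds = QualityThresholds(),
    window=None,
    site_year_id: str = "",
) -> QualityReport:
    """Score one station-year against the inclusion rules.

    The missingness percentage is assessed over the station-year's full
    window (the calendar year as recorded), while ``window`` is the analysis
    window (e.g. January–June) used for the no-data check.  The gap rule
    compares the *full* length of any missing run that intersects
    ``[first_high − h, first_high + h]`` against the threshold and is
    skipped — not failed — when no high day exists.
    """
    analysis_window = _window_or_default(series, window)
    pct = percent_missing(series)
    gap = longest_gap(series)
    fdd = first_data_day(series)
    fhd = first_high_day(series, thresholds.high_threshold)

    reasons: list[str] = []
    lo, hi = analysis_window
    in_window = series.values[lo - 1 : hi]
    if np.all(np.isnan(in_window)):
        reasons.append(REASON_NO_DATA)
    if pct > thresholds.max_pct_missing:
        reasons.append(REASON_MISSINGNESS)

    gap_near_high = 0
    if fhd is not None:
        h = thresholds.high_window_halfwidth
        near_lo, near_hi = fhd - h, fhd + h
        for start, end in missing_runs(series):
            if start <= near_hi and end >= near_lo:  # run intersects interval
                gap_near_high = max(gap_near_high, end - start + 1)
        if gap_near_high > thresholds.max_gap_near_high:
            reasons.append(REASON_GAP_NEAR_HIGH)

    return QualityReport(
        site_year_id=site_year_id,
        pct_missing_days=pct,
        longest_gap_days=gap,
        first_data_day=fdd,
        first_high_day=fhd,
        gap_near_first_high_days=gap_near_high,
        included=not reasons,
        exclusion_reasons=tuple(reasons),
    )
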