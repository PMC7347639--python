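"""Pollen-season onset estimation and search-vs-station discrepancy analysis.

There is no consensus definition of "season start"; this module implements
the common rules side by side:

* ``cumulative_fraction`` — first day the cumulative sum reaches a fraction
  (5% or 2.5%) of the annual total;
* ``consecutive_days`` — first day of the earliest run of N (default 4)
  consecutive observed days with positive counts;
* ``absolute_threshold`` — first day the concentration reaches a level
  (default 200 grains/m³, the clinical "high" threshold).

Station-side cumulative totals run over the full calendar year; search-side
starts use the early-season window sum as their total, since daily search
data only cover the early season.  Missing days contribute zero to
cumulative sums — no imputation anywhere.

The discrepancy analysis mirrors the progressive-inclusion design: the
difference (search start − station start, negative = search leads) is
summarised over all included site-years, then after requiring station data
to begin within January, then additionally requiring < 20% unquantified
search days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import TransformConfig, log_transform, lowess_smooth, restrict_window
from .quality import first_high_day
from .series import DailySeries

__all__ = [
    "StartDefinition",
    "SeasonStart",
    "DiscrepancyRecord",
    "TierSummary",
    "start_cumulative",
    "start_consecutive",
    "start_absolute",
    "season_start",
    "gt_season_start",
    "discrepancy_analysis",
]

VARIANTS = ("raw", "smoothed", "log_smoothed")
TIERS = ("all", "early_nab_data", "low_gt_missing")


@dataclass(frozen=True)
class StartDefinition:
    """A named onset rule plus the data variant it runs on."""

    method: str = "cumulative_fraction"
    fraction: float | None = 0.05
    run_length: int | None = None
    threshold: float | None = None
    variant: str = "raw"
    strict: bool = False  # absolute rule: ">" instead of ">="

    def __post_init__(self) -> None:
        if self.method == "cumulative_fraction":
            if not (self.fraction and 0 < self.fraction < 1):
                raise ValueError("cumulative_fraction needs fraction in (0, 1)")
            if self.run_length is not None or self.threshold is not None:
                raise ValueError("only fraction may be set for cumulative_fraction")
        elif self.method == "consecutive_days":
            if not (self.run_length and self.run_length >= 1):
                raise ValueError("consecutive_days needs run_length >= 1")
            if self.fraction is not None or self.threshold is not None:
                raise ValueError("only run_length may be set for consecutive_days")
        elif self.method == "absolute_threshold":
            if self.threshold is None or self.threshold < 0:
                raise ValueError("absolute_threshold needs threshold >= 0")
            if self.fraction is not None or self.run_length is not None:
                raise ValueError("only threshold may be set for absolute_threshold")
        else:
            raise ValueError(f"unknown onset method {self.method!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def cumulative(cls, fraction: float = 0.05, variant: str = "raw"):
        return cls(method="cumulative_fraction", fraction=fraction, variant=variant)

    @classmethod
    def consecutive(cls, run_length: int = 4, variant: str = "raw"):
        return cls(
            method="consecutive_days", fraction=None,
            run_length=run_length, variant=variant,
        )

    @classmethod
    def absolute(cls, threshold: float = 200.0, variant: str = "raw",
                 strict: bool = False):
        return cls(
            method="absolute_threshold", fraction=None, threshold=threshold,
            variant=variant, strict=strict,
        )

    def label(self) -> str:
        if self.method == "cumulative_fraction":
            return f"cum{self.fraction:g}"
        if self.method == "consecutive_days":
            return f"run{self.run_length}"
        return f"abs{self.threshold:g}"


@dataclass(frozen=True)
class SeasonStart:
    site_year_id: str
    definition: StartDefinition
    start_day: int | None
    basis_total: float | None = None
    flags: tuple[str, ...] = ()


def start_cumulative(
    series: DailySeries,
    fraction: float = 0.05,
    site_year_id: str = "",
    definition: StartDefinition | None = None,
) -> SeasonStart:
    """First day the cumulative sum reaches ``fraction`` of the total.

    The total is summed over the series' whole window (the calendar year for
    station data); missing days contribute 0.  A non-positive total yields
    no start and a ``zero_total`` flag.
    """
    definition = definition or StartDefinition.cumulative(fraction)
    values = np.nan_to_num(series.window_values, nan=0.0)
    # Smoothed variants can undershoot slightly below zero; clip so the
    # cumulative sum stays monotone and the first crossing is well defined.
    values = np.clip(values, 0.0, None)
    total = float(values.sum())
    if total <= 0:
        return SeasonStart(site_year_id, definition, None, total, ("zero_total",))
    cum = np.cumsum(values)
    idx = int(np.searchsorted(cum, fraction * total))
    return SeasonStart(site_year_id, definition, series.window[0] + idx, total)


def start_consecutive(
    series: DailySeries, run_length: int = 4, site_year_id: str = ""
) -> SeasonStart:
    """First day of the earliest run of ``run_length`` observed positive days."""
    definition = StartDefinition.consecutive(run_length)
    values = series.window_values
    positive = np.nan_to_num(values, nan=0.0) > 0
    run = 0
    for offset, ok in enumerate(positive):
        run = run + 1 if ok else 0
        if run >= run_length:
            start = series.window[0] + offset - run_length + 1
            return SeasonStart(site_year_id, definition, start)
    return SeasonStart(site_year_id, definition, None, flags=("no_qualifying_run",))


def start_absolute(
    series: DailySeries,
    threshold: float = 200.0,
    site_year_id: str = "",
    strict: bool = False,
) -> SeasonStart:
    """First observed day at (or strictly above) the concentration threshold."""
    definition = StartDefinition.absolute(threshold, strict=strict)
    if strict:
        values = series.window_values
        with np.errstate(invalid="ignore"):
            idx = np.flatnonzero(values > threshold)
        day = int(series.window[0] + idx[0]) if idx.size else None
    else:
        day = first_high_day(series, threshold)
    flags = () if day is not None else ("threshold_never_reached",)
    return SeasonStart(site_year_id, definition, day, flags=flags)


def season_start(
    series: DailySeries, definition: StartDefinition, site_year_id: str = ""
) -> SeasonStart:
    """Dispatch to the onset rule named by ``definition``."""
    if definition.method == "cumulative_fraction":
        result = start_cumulative(series, definition.fraction, site_year_id)
    elif definition.method == "consecutive_days":
        result = start_consecutive(series, definition.run_length, site_year_id)
    else:
        result = start_absolute(
            series, definition.threshold, site_year_id, definition.strict
        )
    return SeasonStart(
        site_year_id, definition, result.start_day, result.basis_total, result.flags
    )


def _apply_variant(
    series: DailySeries, variant: str, config: TransformConfig
) -> DailySeries:
    if variant == "raw":
        return series
    if variant == "smoothed":
        return lowess_smooth(series, config.lowess_light_bw, config.lowess_iterations)
    if variant == "log_smoothed":
        return lowess_smooth(
            log_transform(series, config.log_offset),
            config.lowess_light_bw,
            config.lowess_iterations,
        )
    raise ValueError(f"unknown variant {variant!r}")


def gt_season_start(
    search: DailySeries,
    definition: StartDefinition | None = None,
    config: TransformConfig = TransformConfig(),
    site_year_id: str = "",
) -> SeasonStart:
    """Season start estimated from a search series.

    The series is restricted to the early-season window, transformed to the
    definition's variant (raw / smoothed / log-smoothed), and the onset rule
    (default: cumulative 5%) is applied with the window sum as the total.
    Censored zeros contribute 0.  An all-zero window yields no start.
    """
    definition = definition or StartDefinition.cumulative(0.05)
    window = config.window_for(search.year)
    windowed = restrict_window(search, window)
    try:
        variant_series = _apply_variant(windowed, definition.variant, config)
    except ValueError:
        return SeasonStart(site_year_id, definition, None, flags=("degenerate",))
    result = season_start(variant_series, definition, site_year_id)
    return result


@dataclass(frozen=True)
class DiscrepancyRecord:
    site_year_id: str
    variant: str
    gt_start: int | None
    nab_start: int | None
    prev_year_nab_start: int | None
    delta_days: float | None           # gt − nab; negative = search leads
    prev_year_delta_days: float | None  # nab − previous-year nab


@dataclass(frozen=True)
class TierSummary:
    tier: str
    n: int
    delta_median_iqr: dict[str, tuple[float, float, float]]
    prev_year_median_iqr: tuple[float, float, float]
    empty: bool = False


def _median_iqr(values: list[float]) -> tuple[float, float, float]:
    if not values:
        return (math.nan, math.nan, math.nan)
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


@dataclass(frozen=True)
class SiteYearOnset:
    """Bundle of per-site-year inputs to the discrepancy analysis."""

    site_year_id: str
    pollen: DailySeries
    search: DailySeries                 # averaged replicates
    gt_pct_missing: float               # % window days unquantified (zeros)
    nab_first_data_day: int | None = None
    prev_year_pollen: DailySeries | None = None


def discrepancy_analysis(
    site_years: list[SiteYearOnset],
    definition: StartDefinition | None = None,
    config: TransformConfig = TransformConfig(),
    variants: tuple[str, ...] = VARIANTS,
    early_nab_cutoff_day: int = 31,
    low_gt_missing_cutoff: float = 20.0,
) -> tuple[list[DiscrepancyRecord], dict[str, TierSummary]]:
    """Search-vs-station onset discrepancies under progressive inclusion.

    Tiers nest: ``all`` site-years; then those whose station record begins
    within the first month of the year; then additionally those with fewer
    than 20% unquantified search days.  Each tier reports the median and
    IQR of delta per data variant, alongside the previous-year station
    baseline (current minus prior-year station start) where a prior year
    exists.
    """
    definition = definition or StartDefinition.cumulative(0.05)
    records: list[DiscrepancyRecord] = []
    meta: dict[str, SiteYearOnset] = {}
    for sy in site_years:
        meta[sy.site_year_id] = sy
        nab = start_cumulative(
            sy.pollen, definition.fraction or 0.05, sy.site_year_id
        ).start_day
        prev = None
        if sy.prev_year_pollen is not None:
            prev = start_cumulative(
                sy.prev_year_pollen, definition.fraction or 0.05, sy.site_year_id
            ).start_day
        for variant in variants:
            vdef = StartDefinition(
                method=definition.method,
                fraction=definition.fraction,
                run_length=definition.run_length,
                threshold=definition.threshold,
                variant=variant,
            )
            gt = gt_season_start(sy.search, vdef, config, sy.site_year_id).start_day
            records.append(
                DiscrepancyRecord(
                    site_year_id=sy.site_year_id,
                    variant=variant,
                    gt_start=gt,
                    nab_start=nab,
                    prev_year_nab_start=prev,
                    delta_days=(gt - nab) if gt is not None and nab is not None
                    else None,
                    prev_year_delta_days=(nab - prev)
                    if nab is not None and prev is not None
                    else None,
                )
            )

    def in_tier(sy: SiteYearOnset, tier: str) -> bool:
        if tier == "all":
            return True
        early = (
            sy.nab_first_data_day is not None
            and sy.nab_first_data_day <= early_nab_cutoff_day
        )
        if tier == "early_nab_data":
            return early
        return early and sy.gt_pct_missing < low_gt_missing_cutoff

    summaries: dict[str, TierSummary] = {}
    for tier in TIERS:
        members = {sid for sid, sy in meta.items() if in_tier(sy, tier)}
        tier_records = [r for r in records if r.site_year_id in members]
        deltas = {
            variant: [
                r.delta_days
                for r in tier_records
                if r.variant == variant and r.delta_days is not None
            ]
            for variant in variants
        }
        prev_deltas = sorted(
            {
                (r.site_year_id, r.prev_year_delta_days)
                for r in tier_records
                if r.prev_year_delta_days is not None
            }
        )
        summaries[tier] = TierSummary(
            tier=tier,
            n=len(members),
            delta_median_iqr={v: _median_iqr(d) for v, d in deltas.items()},
            prev_year_median_iqr=_median_iqr([d for _, d in prev_deltas]),
            empty=not members,
        )
    return records, summaries
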