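"""Rank correlation between search and pollen series, and its covariates.

For each matched site-year the headline statistic is Spearman's rho between
the log-transformed, lightly smoothed search and pollen series, computed
over days where both are observed.  Because the search feed reports
sub-threshold volumes as 0 rather than as true zeros, those censored days
are treated as missing on the search side by default (a flag retains them
for sensitivity runs).

Two covariates stratify the results into quartiles:

* the fraction of window days the search feed left unquantified (zeros),
  a data-volume proxy tied to market population; and
* the peak signal-to-noise statistic — the mean absolute difference between
  the (log-scale) daily series and its heavily smoothed (bandwidth 0.8)
  LOWESS baseline, large when the season produces one distinct search peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .preprocess import (
    TransformConfig,
    log_transform,
    lowess_smooth,
    normalize_to_max,
    restrict_window,
)
from .series import DailySeries, RegionYear, StationYear

__all__ = [
    "AssociationResult",
    "GroupComparison",
    "CovariateScreen",
    "spearman_rho",
    "peak_snr",
    "associate_pair",
    "quartile_stratify",
    "QuartileSummary",
    "compare_groups",
    "screen_covariate",
]


@dataclass(frozen=True)
class AssociationResult:
    site_year_id: str
    rho: float | None            # None when fewer than 3 joint days
    n_days: int
    pct_gt_zero_days: float      # % of window days with search value 0
    pct_gt_missing_days: float   # % of window days truly missing in the feed
    peak_snr: float | None
    quartile_by_missing: int | None = None
    quartile_by_snr: int | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    summary_a: tuple[float, float, float]  # median, q1, q3
    summary_b: tuple[float, float, float]


@dataclass(frozen=True)
class CovariateScreen:
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    p_value: float


def _median_iqr(values) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan, math.nan)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


def spearman_rho(x: DailySeries, y: DailySeries) -> tuple[float | None, int]:
    """Spearman rank correlation over jointly observed days.

    Ties receive average ranks.  Returns ``(rho, n_days)``; rho is None when
    fewer than 3 days are jointly observed or either side is constant.
    """
    if x.year != y.year:
        raise ValueError("series must share a calendar year")
    joint = x.observed_mask & y.observed_mask
    n = int(joint.sum())
    if n < 3:
        return None, n
    xv, yv = x.values[joint], y.values[joint]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return None, n
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho), n


def peak_snr(
    search_raw: DailySeries,
    heavy_bw: float = 0.8,
    scale: str = "log",
    log_offset: float = 1.0,
) -> float:
    """Mean absolute deviation of a search series from its slow baseline.

    The series (log1p scale by default; ``scale="raw"`` for untransformed
    volumes) is heavily LOWESS-smoothed (bandwidth ``heavy_bw``) to estimate
    baseline fluctuation, and the statistic is the mean |value − baseline|
    over observed days.  Site-years with a single prominent search peak
    deviate strongly from their baseline and score high.
    """
    if scale not in ("log", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    series = search_raw
    if scale == "log":
        series = log_transform(search_raw, log_offset)
    smooth = lowess_smooth(series, heavy_bw)
    mask = series.observed_mask
    return float(np.mean(np.abs(series.values[mask] - smooth.values[mask])))


def _mask_search_zeros(series: DailySeries) -> DailySeries:
    values = np.where(series.values == 0, np.nan, series.values)
    return series.with_values(values)


def associate_pair(
    station: StationYear,
    region: RegionYear,
    config: TransformConfig = TransformConfig(),
    censored_zeros_as_missing: bool = True,
) -> AssociationResult:
    """Full correlation pathway for one matched site-year.

    Both series are restricted to the early-season window; pollen is
    normalised to a maximum of 100; censored search zeros become missing
    (by default); both sides are log-transformed and lightly smoothed
    (bandwidth 0.1); Spearman's rho is computed pairwise-complete.  The
    search-side covariates (zero fraction, true missingness, peak SNR) are
    measured on the windowed averaged replicate series before any masking.
    """
    window = config.window_for(station.series.year)
    flags: list[str] = []

    search_w = restrict_window(region.averaged, window)
    sv = search_w.window_values
    pct_zero = 100.0 * float(np.sum(sv == 0)) / sv.size
    pct_missing = 100.0 * float(np.sum(np.isnan(sv))) / sv.size

    try:
        snr = peak_snr(search_w, config.lowess_heavy_bw, log_offset=config.log_offset)
    except ValueError:
        snr = None
        flags.append("degenerate_search")

    pollen_w = restrict_window(station.series, window)
    try:
        pollen_t = normalize_to_max(pollen_w, config.normalize_max)
    except ValueError:
        flags.append("degenerate_pollen")
        return AssociationResult(
            site_year_id=f"{station.station_id}|{region.dma_id}:{station.series.year}",
            rho=None, n_days=0, pct_gt_zero_days=pct_zero,
            pct_gt_missing_days=pct_missing, peak_snr=snr, flags=tuple(flags),
        )
    search_t = _mask_search_zeros(search_w) if censored_zeros_as_missing else search_w

    def _log_smooth(series: DailySeries) -> DailySeries:
        series = log_transform(series, config.log_offset)
        return lowess_smooth(series, config.lowess_light_bw, config.lowess_iterations)

    try:
        pollen_t = _log_smooth(pollen_t)
        search_t = _log_smooth(search_t)
    except ValueError:
        flags.append("too_few_days")
        rho, n = None, 0
    else:
        rho, n = spearman_rho(search_t, pollen_t)
        if rho is None:
            flags.append("too_few_joint_days")

    return AssociationResult(
        site_year_id=f"{station.station_id}|{region.dma_id}:{station.series.year}",
        rho=rho,
        n_days=n,
        pct_gt_zero_days=pct_zero,
        pct_gt_missing_days=pct_missing,
        peak_snr=snr,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class QuartileSummary:
    by: str
    cutoffs: tuple[float, float, float]
    assignments: dict[str, int]
    rho_median_iqr: dict[int, tuple[float, float, float]]
    degenerate_cutoffs: bool = False


_COVARIATES = {
    "pct_missing": "pct_gt_zero_days",
    "pct_gt_zero_days": "pct_gt_zero_days",
    "pct_gt_missing_days": "pct_gt_missing_days",
    "peak_snr": "peak_snr",
}


def quartile_stratify(
    results: list[AssociationResult], by: str = "pct_missing"
) -> tuple[list[AssociationResult], QuartileSummary]:
    """Assign site-years to quartiles of a covariate and summarise rho.

    Cutoffs are the 25th/50th/75th percentiles (linear interpolation between
    order statistics) of the covariate over site-years where it is defined;
    a value ≤ the 25th percentile lands in Q1, ≤ median in Q2, ≤ 75th in
    Q3, else Q4.  Returns results annotated with their quartile plus the
    per-quartile median and IQR of rho.
    """
    attr = _COVARIATES.get(by)
    if attr is None:
        raise ValueError(f"unknown stratification covariate {by!r}")
    usable = [r for r in results if getattr(r, attr) is not None]
    if len(usable) < 4:
        raise ValueError("need at least 4 site-years to form quartiles")
    values = np.array([getattr(r, attr) for r in usable], dtype=float)
    cutoffs = tuple(float(c) for c in np.percentile(values, [25, 50, 75]))
    degenerate = cutoffs[0] == cutoffs[2]

    def quartile(v: float) -> int:
        if v <= cutoffs[0]:
            return 1
        if v <= cutoffs[1]:
            return 2
        if v <= cutoffs[2]:
            return 3
        return 4

    field = "quartile_by_snr" if attr == "peak_snr" else "quartile_by_missing"
    annotated: list[AssociationResult] = []
    assignments: dict[str, int] = {}
    rho_by_q: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    for r in results:
        v = getattr(r, attr)
        if v is None:
            annotated.append(r)
            continue
        q = quartile(float(v))
        assignments[r.site_year_id] = q
        annotated.append(replace(r, **{field: q}))
        if r.rho is not None:
            rho_by_q[q].append(r.rho)
    summary = QuartileSummary(
        by=by,
        cutoffs=cutoffs,
        assignments=assignments,
        rho_median_iqr={q: _median_iqr(v) for q, v in rho_by_q.items()},
        degenerate_cutoffs=degenerate,
    )
    return annotated, summary


def compare_groups(
    a, b, label_a: str = "a", label_b: str = "b", welch: bool = False
) -> GroupComparison:
    """Two-sample t-test on rho collections (pooled variance by default)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_a=_median_iqr(a),
        summary_b=_median_iqr(b),
    )


def screen_covariate(x, y, log_x: bool = False) -> CovariateScreen:
    """Univariate OLS screen of a per-site covariate against a metric.

    Returns Pearson r, slope/intercept, R², the normal-theory 95% CI of the
    slope, and the two-sided p-value.  ``log_x`` applies a natural log to
    the covariate first (market-size screens run on log TV-homes).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if log_x:
        x = np.log(x)
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return CovariateScreen(
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci=(float(ci[0]), float(ci[1])),
        p_value=float(res.pvalue),
    )
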