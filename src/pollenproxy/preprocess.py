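"""Transforms applied before correlation and onset analyses.

The comparison pathway for a matched site-year is: restrict both series to
the early season (January–June), normalise the pollen series to a maximum
of 100 so both sources share a scale, log-transform (offset 1, both contain
zeros), then lightly smooth with LOWESS at bandwidth 0.1.  A heavy LOWESS
(bandwidth 0.8) supplies the slow baseline used by the peak signal-to-noise
statistic.

The LOWESS here is the classical locally weighted scatterplot smoother:
for each target day the nearest ``ceil(bandwidth · n)`` observed days form
the neighbourhood, tricube weights decay with distance to the farthest
neighbour, and a weighted *linear* fit is evaluated at the target.  The
bandwidth is the fraction of observed points per neighbourhood; robustness
iterations default to 0.  Local-linear fits reproduce straight lines
exactly, which downstream statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TRANSFORMED, DailySeries, jan_jun_window

__all__ = [
    "TransformConfig",
    "restrict_window",
    "normalize_to_max",
    "log_transform",
    "lowess_smooth",
    "lowess_fit",
]


@dataclass(frozen=True)
class TransformConfig:
    """Transform-stack settings; defaults are the study's operating values.

    ``window=None`` means January–June of the series' own year.
    """

    window: tuple[int, int] | None = None
    normalize_max: float = 100.0
    log_offset: float = 1.0
    lowess_light_bw: float = 0.1
    lowess_heavy_bw: float = 0.8
    lowess_iterations: int = 0

    def __post_init__(self) -> None:
        for name in ("lowess_light_bw", "lowess_heavy_bw"):
            bw = getattr(self, name)
            if not 0 < bw <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {bw}")
        if not self.log_offset > 0:
            raise ValueError("log_offset must be positive")
        if self.lowess_iterations < 0:
            raise ValueError("lowess_iterations must be >= 0")

    def window_for(self, year: int) -> tuple[int, int]:
        return self.window if self.window is not None else jan_jun_window(year)


def restrict_window(series: DailySeries, window: tuple[int, int]) -> DailySeries:
    """Drop days outside ``window``; missingness inside is preserved.

    An empty intersection with the series' current window raises.
    """
    lo = max(int(window[0]), series.window[0])
    hi = min(int(window[1]), series.window[1])
    if lo > hi:
        raise ValueError(
            f"window {window} does not intersect series window {series.window}"
        )
    values = series.values.copy()
    values[: lo - 1] = np.nan
    values[hi:] = np.nan
    return series.with_values(values, window=(lo, hi))


def normalize_to_max(series: DailySeries, target: float = 100.0) -> DailySeries:
    """Rescale so the maximum observed value equals ``target`` exactly."""
    observed = series.window_values
    peak = np.nanmax(observed) if not np.all(np.isnan(observed)) else 0.0
    if not peak > 0:
        raise ValueError("degenerate series: no positive observed value")
    return series.with_values(series.values * (target / peak))


def log_transform(series: DailySeries, offset: float = 1.0) -> DailySeries:
    """v -> ln(v + offset) on observed days; missing days stay missing."""
    if not offset > 0:
        raise ValueError("offset must be positive")
    with np.errstate(invalid="ignore"):
        values = np.log(series.values + offset)
    return series.with_values(values, kind=TRANSFORMED)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    frac: float,
    iterations: int = 0,
) -> np.ndarray:
    """Classical LOWESS fitted values at each ``x``.

    ``x`` must be sorted ascending.  Neighbourhood size is
    ``ceil(frac · n)`` (clamped to [2, n]); weights are tricube in distance
    scaled by the farthest neighbour; each fit is weighted linear.
    ``iterations`` > 0 adds bisquare robustness reweighting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    k = min(max(int(np.ceil(frac * n)), 2), n)
    robust = np.ones(n)
    fitted = y.copy()
    for iteration in range(iterations + 1):
        fitted = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            # Stable argsort: among tied distances the leftmost point wins,
            # matching the sliding-window convention of reference LOWESS codes.
            nbr = np.argsort(d, kind="stable")[:k]
            h = d[nbr].max()
            if h == 0:
                w = robust[nbr]
            else:
                w = _tricube(d[nbr] / h) * robust[nbr]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = y[nbr].mean()
                continue
            xb = (w * x[nbr]).sum() / sw
            yb = (w * y[nbr]).sum() / sw
            sxx = (w * (x[nbr] - xb) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xb * xb):
                fitted[i] = yb
            else:
                slope = (w * (x[nbr] - xb) * (y[nbr] - yb)).sum() / sxx
                fitted[i] = yb + slope * (x[i] - xb)
        if iteration < iterations:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust = (1.0 - np.clip(resid / (6.0 * s), -1, 1) ** 2) ** 2
    return fitted


def lowess_smooth(
    series: DailySeries, bandwidth: float, iterations: int = 0
) -> DailySeries:
    """LOWESS-smooth a daily series over its observed days only.

    Fitted values replace observations at observed days; missing days remain
    missing.  Requires at least 5 observed points.
    """
    if not 0 < bandwidth <= 1:
        raise ValueError(f"bandwidth must lie in (0, 1], got {bandwidth}")
    mask = series.observed_mask
    if mask.sum() < 5:
        raise ValueError("too few observed points for smoothing (need >= 5)")
    days = np.flatnonzero(mask) + 1.0
    fitted = lowess_fit(days, series.values[mask], bandwidth, iterations)
    values = np.full_like(series.values, np.nan)
    values[mask] = fitted
    return series.with_values(values, kind=TRANSFORMED)
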