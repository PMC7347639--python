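"""Coupled synthetic pollen / search-volume panels.

The real data behind this kind of proxy-validation study are hard to obtain:
station pollen counts are released only on written request, and search feeds
are rescaled, integer-quantised and zero-censored in ways the consumer cannot
undo.  This module generates site-year panels with the statistical structure
the analysis assumes, so every downstream stage can be exercised and tested:

* a bimodal annual pollen season — one dominant Gaussian peak early in the
  year (tree pollen) and a smaller one later (grass/weed) — on a small
  baseline, with multiplicative lognormal daily noise;
* station missingness emulating weekend skips, year-edge gaps and random
  collection gaps;
* search series that are a lagged monotone (power-law) response to the
  *complete* pollen signal plus a baseline search floor, zero-censored below
  a display threshold, independently rescaled per download replicate to a
  maximum of 100 and rounded to integers, with inter-replicate sampling
  noise.

All randomness flows from a single seed through `numpy.random.SeedSequence`,
so a fixed `PanelSpec` reproduces its panel bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .series import (
    POLLEN,
    SEARCH,
    DailySeries,
    RegionYear,
    StationYear,
    weekend_days,
    year_length,
)

__all__ = [
    "PollenModelParams",
    "SearchModelParams",
    "MissingnessParams",
    "PanelSpec",
    "pollen_expected_curve",
    "generate_pollen_year",
    "generate_search_year",
    "generate_panel",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class PollenModelParams:
    """Shape and noise of the annual pollen-concentration curve.

    The expected concentration on day *d* is
    ``baseline + Σ_i amplitude_i · exp(−(d − peak_i_day)² / (2 · width_i²))``
    and observed values multiply that by lognormal noise with coefficient of
    variation ``noise_cv`` (mean 1, so the expectation is preserved).
    """

    peak1_day: float = 95.0        # dominant early-season (tree) peak
    peak1_width_days: float = 12.0
    peak1_amplitude: float = 800.0  # grains/m³ above baseline at the mode
    peak2_day: float = 240.0        # smaller late-season peak
    peak2_width_days: float = 20.0
    peak2_amplitude: float = 250.0
    noise_cv: float = 0.4
    baseline: float = 2.0           # off-season floor, grains/m³

    def __post_init__(self) -> None:
        _require(self.peak1_width_days > 0, "peak1_width_days must be > 0")
        _require(self.peak2_width_days > 0, "peak2_width_days must be > 0")
        _require(1 <= self.peak1_day <= 366, "peak1_day must lie in 1..366")
        _require(1 <= self.peak2_day <= 366, "peak2_day must lie in 1..366")
        _require(self.peak1_amplitude >= 0, "peak1_amplitude must be >= 0")
        _require(self.peak2_amplitude >= 0, "peak2_amplitude must be >= 0")
        _require(
            self.peak2_amplitude == 0 or self.peak1_amplitude > self.peak2_amplitude,
            "peak1_amplitude must exceed peak2_amplitude (dominant early peak)",
        )
        _require(self.noise_cv >= 0, "noise_cv must be >= 0")
        _require(self.baseline >= 0, "baseline must be >= 0")


@dataclass(frozen=True)
class SearchModelParams:
    """Coupling of regional search volume to the pollen signal.

    The latent (pre-display) volume on day *d* is
    ``noise(d) · (baseline_rate + pollen(d − lag_days)^response_exponent)``.
    Latent values below ``censor_threshold`` are reported as 0 *before* the
    per-replicate rescaling to a maximum of 100, mirroring how public search
    feeds suppress low absolute volumes.
    """

    lag_days: int = 0
    response_exponent: float = 0.7  # sublinear symptom/attention response
    baseline_rate: float = 10.0     # off-season search floor, latent units
    noise_cv: float = 0.25
    censor_threshold: float = 12.0
    n_replicates: int = 10
    replicate_noise_cv: float = 0.3

    def __post_init__(self) -> None:
        _require(self.response_exponent > 0, "response_exponent must be > 0")
        _require(self.baseline_rate >= 0, "baseline_rate must be >= 0")
        _require(self.noise_cv >= 0, "noise_cv must be >= 0")
        _require(self.censor_threshold >= 0, "censor_threshold must be >= 0")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")
        _require(self.replicate_noise_cv >= 0, "replicate_noise_cv must be >= 0")


@dataclass(frozen=True)
class MissingnessParams:
    """Station-compliance missingness: weekends, year edges, random gaps."""

    weekend_missing_prob: float = 0.7
    edge_gap_days: tuple[int, int] = (3, 7)  # unmeasured days at year start/end
    random_gap_rate: float = 5.0             # expected random gaps per year
    random_gap_length_mean: float = 3.0      # mean gap length, days

    def __post_init__(self) -> None:
        _require(
            0 <= self.weekend_missing_prob <= 1,
            "weekend_missing_prob must lie in [0, 1]",
        )
        _require(
            self.edge_gap_days[0] >= 0 and self.edge_gap_days[1] >= 0,
            "edge_gap_days must be >= 0",
        )
        _require(self.random_gap_rate >= 0, "random_gap_rate must be >= 0")
        _require(
            self.random_gap_length_mean >= 1 or self.random_gap_rate == 0,
            "random_gap_length_mean must be >= 1",
        )

    @classmethod
    def none(cls) -> "MissingnessParams":
        """Fully observed year (all missingness mechanisms off)."""
        return cls(
            weekend_missing_prob=0.0,
            edge_gap_days=(0, 0),
            random_gap_rate=0.0,
        )


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a reproducible panel of coupled site-years.

    Per-site heterogeneity (peak timing, season strength, market size) is
    drawn from the spec's seed, so an identical spec yields a bit-identical
    panel.  When ``censor_tv_homes_ref`` is set, each region's censor
    threshold is the base threshold scaled by ``ref / tv_homes`` — small
    markets lose more days to zero-censoring, the mechanism behind the
    data-volume effect the analysis stratifies on.
    """

    n_site_years: int = 20
    year: int = 2015
    seed: int = 0
    pollen: PollenModelParams = field(default_factory=PollenModelParams)
    search: SearchModelParams = field(default_factory=SearchModelParams)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    peak_day_jitter_sd: float = 10.0   # per-site shift of both peaks, days
    amplitude_jitter_cv: float = 0.3   # lognormal per-site amplitude factor
    censor_tv_homes_ref: float | None = None
    lat_range: tuple[float, float] = (25.0, 49.0)    # continental US
    lon_range: tuple[float, float] = (-124.0, -67.0)
    tv_homes_range: tuple[float, float] = (3e4, 3e6)  # log-uniform

    def __post_init__(self) -> None:
        _require(self.n_site_years >= 1, "n_site_years must be >= 1")
        _require(self.peak_day_jitter_sd >= 0, "peak_day_jitter_sd must be >= 0")
        _require(self.amplitude_jitter_cv >= 0, "amplitude_jitter_cv must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def pollen_expected_curve(params: PollenModelParams, year: int) -> np.ndarray:
    """Noise-free expected concentration for each day of ``year``."""
    days = np.arange(1, year_length(year) + 1, dtype=float)
    curve = np.full_like(days, params.baseline)
    for day, width, amp in (
        (params.peak1_day, params.peak1_width_days, params.peak1_amplitude),
        (params.peak2_day, params.peak2_width_days, params.peak2_amplitude),
    ):
        curve += amp * np.exp(-((days - day) ** 2) / (2.0 * width * width))
    return curve


def _complete_pollen_values(
    params: PollenModelParams, year: int, rng: np.random.Generator
) -> np.ndarray:
    curve = pollen_expected_curve(params, year)
    return curve * _lognormal_factors(rng, params.noise_cv, curve.size)


def _missing_mask(
    missingness: MissingnessParams, year: int, rng: np.random.Generator
) -> np.ndarray:
    n = year_length(year)
    missing = np.zeros(n, dtype=bool)
    wkd = weekend_days(year)
    if missingness.weekend_missing_prob > 0:
        hit = rng.random(wkd.size) < missingness.weekend_missing_prob
        missing[wkd[hit] - 1] = True
    start_gap, end_gap = missingness.edge_gap_days
    missing[: min(start_gap, n)] = True
    if end_gap > 0:
        missing[-min(end_gap, n):] = True
    if missingness.random_gap_rate > 0:
        n_gaps = rng.poisson(missingness.random_gap_rate)
        for _ in range(n_gaps):
            length = rng.geometric(1.0 / missingness.random_gap_length_mean)
            start = rng.integers(0, n)
            missing[start : min(start + length, n)] = True
    return missing


def generate_pollen_year(
    params: PollenModelParams,
    year: int,
    missingness: MissingnessParams,
    seed,
) -> DailySeries:
    """One station-year of daily pollen concentrations with missingness.

    ``seed`` may be an int or a `numpy.random.Generator`.  Missing days carry
    NaN, never zero — an unmeasured day is not a pollen-free day.
    """
    if not 1 <= year <= 9999:
        raise ValueError(f"invalid year: {year}")
    rng = np.random.default_rng(seed)
    values = _complete_pollen_values(params, year, rng)
    missing = _missing_mask(missingness, year, rng)
    values = np.where(missing, np.nan, values)
    return DailySeries(year=year, values=values, kind=POLLEN)


def _latent_search(
    pollen_values: np.ndarray, params: SearchModelParams
) -> np.ndarray:
    """Noise-free latent search volume from a (complete) pollen trace.

    Days whose lagged pollen value is missing or falls outside the year
    contribute no pollen-driven searches (the power term is 0 there).
    """
    driver = np.nan_to_num(pollen_values, nan=0.0)
    lag = params.lag_days
    shifted = np.zeros_like(driver)
    if lag >= 0:
        if lag < driver.size:
            shifted[lag:] = driver[: driver.size - lag]
    else:
        if -lag < driver.size:
            shifted[: driver.size + lag] = driver[-lag:]
    return params.baseline_rate + np.power(shifted, params.response_exponent)


def generate_search_year(
    pollen: DailySeries, params: SearchModelParams, seed
) -> list[DailySeries]:
    """Simulated download replicates of the search feed for one region-year.

    Each replicate shares the day-level search signal (lagged power-law
    response to pollen times daily noise) and adds its own sampling noise;
    censoring to 0 happens on the latent scale *before* each replicate is
    rescaled to max 100 and rounded half-up to integers.  A replicate whose
    every latent value is censored comes back all-zero with an
    ``"all_censored"`` flag rather than an error — sparse markets do this.
    """
    rng = np.random.default_rng(seed)
    n = pollen.values.size
    base = _latent_search(pollen.values, params)
    day_noise = _lognormal_factors(rng, params.noise_cv, n)
    signal = base * day_noise
    replicates: list[DailySeries] = []
    for _ in range(params.n_replicates):
        latent = signal * _lognormal_factors(rng, params.replicate_noise_cv, n)
        reported = np.where(latent < params.censor_threshold, 0.0, latent)
        peak = reported.max()
        flags: tuple[str, ...] = ()
        if peak <= 0:
            flags = ("all_censored",)
            scaled = np.zeros(n)
        else:
            scaled = np.floor(reported * (100.0 / peak) + 0.5)  # round half-up
        replicates.append(
            DailySeries(year=pollen.year, values=scaled, kind=SEARCH, flags=flags)
        )
    return replicates


def generate_panel(spec: PanelSpec) -> list[tuple[StationYear, RegionYear]]:
    """A reproducible panel of matched (station-year, region-year) pairs.

    The search series respond to the *complete* (pre-missingness) pollen
    signal: internet users react to airborne pollen, not to whether a
    counting station staffed its sampler that day.  Station and region carry
    nearly identical coordinates (within the matching tolerance downstream).
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_site_years)
    pairs: list[tuple[StationYear, RegionYear]] = []
    for i, child in enumerate(children):
        site_rng = np.random.default_rng(child)
        shift = site_rng.normal(0.0, spec.peak_day_jitter_sd)
        amp_factor = _lognormal_factors(site_rng, spec.amplitude_jitter_cv, 1)[0]
        n_year = year_length(spec.year)
        pollen_params = dataclasses.replace(
            spec.pollen,
            peak1_day=float(np.clip(spec.pollen.peak1_day + shift, 1, n_year)),
            peak2_day=float(np.clip(spec.pollen.peak2_day + shift, 1, n_year)),
            peak1_amplitude=spec.pollen.peak1_amplitude * amp_factor,
            peak2_amplitude=spec.pollen.peak2_amplitude * amp_factor,
        )
        lat = site_rng.uniform(*spec.lat_range)
        lon = site_rng.uniform(*spec.lon_range)
        log_lo, log_hi = np.log(spec.tv_homes_range[0]), np.log(spec.tv_homes_range[1])
        tv_homes = float(np.exp(site_rng.uniform(log_lo, log_hi)))
        search_params = spec.search
        if spec.censor_tv_homes_ref is not None:
            search_params = dataclasses.replace(
                spec.search,
                censor_threshold=spec.search.censor_threshold
                * spec.censor_tv_homes_ref
                / tv_homes,
            )

        complete = _complete_pollen_values(pollen_params, spec.year, site_rng)
        missing = _missing_mask(spec.missingness, spec.year, site_rng)
        observed = DailySeries(
            year=spec.year,
            values=np.where(missing, np.nan, complete),
            kind=POLLEN,
        )
        complete_series = DailySeries(year=spec.year, values=complete, kind=POLLEN)
        replicates = generate_search_year(complete_series, search_params, site_rng)

        station = StationYear(
            station_id=f"S{i:03d}", latitude=lat, longitude=lon, series=observed
        )
        # Region centroid sits a hair off the station, inside the 0.3° rule.
        region = RegionYear(
            dma_id=f"D{i:03d}",
            latitude=lat + site_rng.uniform(-0.2, 0.2),
            longitude=lon + site_rng.uniform(-0.2, 0.2),
            tv_homes=tv_homes,
            replicates=tuple(replicates),
        )
        pairs.append((station, region))
    return pairs
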