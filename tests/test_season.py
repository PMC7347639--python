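import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenproxy.season import (
    SiteYearOnset,
    StartDefinition,
    discrepancy_analysis,
    gt_season_start,
    season_start,
    start_absolute,
    start_consecutive,
    start_cumulative,
)
from pollenproxy.series import SEARCH
from pollenproxy.synthetic import (
    MissingnessParams,
    PanelSpec,
    PollenModelParams,
    SearchModelParams,
    generate_panel,
    generate_pollen_year,
)

from conftest import make_series
from oracles import (
    start_absolute_scan,
    start_consecutive_scan,
    start_cumulative_scan,
)


class TestStartDefinitions:
    def test_exactly_one_parameter_set_allowed(self):
        with pytest.raises(ValueError):
            StartDefinition(method="cumulative_fraction", fraction=0.05,
                            run_length=4)
        with pytest.raises(ValueError, match="unknown onset method"):
            StartDefinition(method="first_rain")
        assert StartDefinition.consecutive(4).run_length == 4


class TestCumulativeStart:
    def test_uniform_block_reaches_five_percent_on_day_one(self):
        series = make_series(fill=0.0,
                             day_values={d: 10.0 for d in range(1, 11)})
        result = start_cumulative(series, 0.05)
        assert result.start_day == 1
        assert result.basis_total == pytest.approx(100.0)

    def test_single_spike_is_start_for_any_fraction(self):
        series = make_series(fill=0.0, day_values={50: 500.0})
        for fraction in (0.01, 0.025, 0.05, 0.5, 0.99):
            assert start_cumulative(series, fraction).start_day == 50

    def test_zero_total_flagged(self):
        result = start_cumulative(make_series(fill=0.0), 0.05)
        assert result.start_day is None
        assert "zero_total" in result.flags

    def test_scale_invariance(self, rng):
        values = rng.gamma(1, 20, 365)
        a = make_series(day_values={i + 1: v for i, v in enumerate(values)})
        b = make_series(day_values={i + 1: 7.3 * v for i, v in enumerate(values)})
        assert start_cumulative(a, 0.05).start_day == \
            start_cumulative(b, 0.05).start_day


class TestConsecutiveAndAbsolute:
    def test_isolated_run_found(self):
        series = make_series(fill=0.0,
                             day_values={d: 3.0 for d in range(30, 34)})
        assert start_consecutive(series, 4).start_day == 30

    def test_alternating_days_never_qualify(self):
        series = make_series(fill=0.0,
                             day_values={d: 5.0 for d in range(1, 365, 2)})
        result = start_consecutive(series, 4)
        assert result.start_day is None

    def test_missing_day_breaks_a_run(self):
        series = make_series(fill=1.0, day_values={32: np.nan})
        assert start_consecutive(series, 4).start_day == 1
        gap_start = make_series(fill=0.0,
                                day_values={**{d: 1.0 for d in range(1, 9)},
                                            **{4: np.nan}})
        assert start_consecutive(gap_start, 4).start_day == 5

    def test_absolute_threshold_comparators(self):
        series = make_series(fill=10.0, day_values={80: 200.0, 90: 300.0})
        assert start_absolute(series, 200.0).start_day == 80
        assert start_absolute(series, 200.0, strict=True).start_day == 90


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_all_rules_match_linear_scan_oracles(seed):
    rng = np.random.default_rng(seed)
    params = PollenModelParams(
        peak1_day=float(rng.integers(40, 160)),
        noise_cv=float(rng.uniform(0, 0.8)),
    )
    series = generate_pollen_year(params, 2015, MissingnessParams(), seed=rng)
    values = series.values.tolist()
    assert start_cumulative(series, 0.05).start_day == \
        start_cumulative_scan(values, 0.05)
    assert start_cumulative(series, 0.025).start_day == \
        start_cumulative_scan(values, 0.025)
    assert start_consecutive(series, 4).start_day == \
        start_consecutive_scan(values, 4)
    assert start_absolute(series, 200.0).start_day == \
        start_absolute_scan(values, 200.0)
    # Monotonicity in the cumulative fraction.
    s_small = start_cumulative(series, 0.025).start_day
    s_large = start_cumulative(series, 0.05).start_day
    if s_small is not None and s_large is not None:
        assert s_small <= s_large


def test_noiseless_generator_onset_recovered_exactly():
    params = PollenModelParams(
        peak1_day=100, peak1_width_days=10, peak1_amplitude=1000,
        peak2_amplitude=0.0, noise_cv=0.0, baseline=0.0,
    )
    series = generate_pollen_year(params, 2015, MissingnessParams.none(), seed=0)
    expected = start_cumulative_scan(series.values.tolist(), 0.05)
    assert start_cumulative(series, 0.05).start_day == expected
    assert season_start(series, StartDefinition.cumulative(0.05)).start_day == \
        expected


class TestGtSeasonStart:
    def test_proportional_search_matches_pollen_start(self):
        values = {d: 0.0 for d in range(1, 366)}
        for d in range(60, 120):
            values[d] = float(d - 59)
        pollen = make_series(day_values=values)
        search = make_series(
            kind=SEARCH,
            day_values={d: v * 100.0 / 60.0 for d, v in values.items()},
        )
        nab = start_cumulative(pollen, 0.05).start_day
        # Window totals coincide because all mass is inside January-June.
        gt = gt_season_start(search).start_day
        assert gt == nab

    def test_planted_shift_recovered(self):
        base = {d: 0.0 for d in range(1, 366)}
        for d in range(60, 100):
            base[d] = 50.0
        pollen = make_series(day_values=base)
        shifted = make_series(
            kind=SEARCH, day_values={min(d + 7, 365): v for d, v in base.items()}
        )
        delta = gt_season_start(shifted).start_day - \
            start_cumulative(pollen, 0.05).start_day
        assert delta == 7

    def test_constant_floor_pulls_start_earlier(self):
        peak = {d: 0.0 for d in range(1, 366)}
        for d in range(90, 120):
            peak[d] = 80.0
        bare = make_series(kind=SEARCH, day_values=peak)
        floored = make_series(
            kind=SEARCH, day_values={d: min(v + 15.0, 100.0)
                                     for d, v in peak.items()}
        )
        assert gt_season_start(floored).start_day < gt_season_start(bare).start_day

    def test_all_zero_window_flagged(self):
        silent = make_series(kind=SEARCH, fill=0.0)
        result = gt_season_start(silent)
        assert result.start_day is None
        assert "zero_total" in result.flags


class TestDiscrepancyAnalysis:
    @staticmethod
    def _panel(n=6, seed=4):
        spec = PanelSpec(
            n_site_years=n, seed=seed,
            pollen=dataclasses.replace(PollenModelParams(), peak2_amplitude=0.0),
            search=SearchModelParams(response_exponent=1.0, baseline_rate=0.0,
                                     censor_threshold=0.0),
        )
        out = []
        for i, (station, region) in enumerate(generate_panel(spec)):
            out.append(
                SiteYearOnset(
                    site_year_id=station.site_year_id,
                    pollen=station.series,
                    search=region.averaged,
                    gt_pct_missing=float(5 + 10 * i),
                    nab_first_data_day=1 if i % 2 == 0 else 60,
                )
            )
        return out

    def test_identical_sources_give_zero_deltas(self):
        site_years = self._panel()
        # Search == pollen (identity coupling, no lag): deltas cluster at ~0.
        records, summaries = discrepancy_analysis(
            site_years, variants=("raw",)
        )
        med, lo, hi = summaries["all"].delta_median_iqr["raw"]
        assert abs(med) <= 2

    def test_tier_membership_matches_hand_computation(self):
        site_years = self._panel(n=6)
        _, summaries = discrepancy_analysis(site_years, variants=("raw",))
        # Even indices have first data day 1 (early); among those, gt missing
        # 5, 25, 45 -> below 20% only the first.
        assert summaries["all"].n == 6
        assert summaries["early_nab_data"].n == 3
        assert summaries["low_gt_missing"].n == 1

    def test_empty_tier_flagged(self):
        site_years = [
            dataclasses.replace(sy, nab_first_data_day=90)
            for sy in self._panel(n=4)
        ]
        _, summaries = discrepancy_analysis(site_years, variants=("raw",))
        assert summaries["early_nab_data"].empty
        assert np.isnan(summaries["early_nab_data"].delta_median_iqr["raw"][0])

    def test_previous_year_baseline_delta(self):
        site_years = self._panel(n=3)
        with_prev = [
            dataclasses.replace(sy, prev_year_pollen=sy.pollen)
            for sy in site_years
        ]
        _, summaries = discrepancy_analysis(with_prev, variants=("raw",))
        # Previous year identical to current year -> baseline delta 0.
        assert summaries["all"].prev_year_median_iqr[0] == pytest.approx(0.0)
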