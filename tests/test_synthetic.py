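import dataclasses

import numpy as np
import pytest
from scipy import stats

from pollenproxy.synthetic import (
    MissingnessParams,
    PanelSpec,
    PollenModelParams,
    SearchModelParams,
    generate_panel,
    generate_pollen_year,
    generate_search_year,
    pollen_expected_curve,
)

from oracles import ols_closed_form, weekend_days_oracle

NOISELESS = PollenModelParams(
    peak1_day=100, peak1_width_days=10, peak1_amplitude=1000,
    peak2_amplitude=0.0, noise_cv=0.0, baseline=0.0,
)
NO_MISSING = MissingnessParams.none()


class TestPollenGeneration:
    def test_noiseless_gaussian_bump_evaluates_analytically(self):
        series = generate_pollen_year(NOISELESS, 2015, NO_MISSING, seed=0)
        assert series.value_on(100) == pytest.approx(1000.0)
        assert series.value_on(250) < 1.0
        # Expected curve matches the closed form at an off-peak day.
        curve = pollen_expected_curve(NOISELESS, 2015)
        assert curve[119] == pytest.approx(1000 * np.exp(-(20**2) / (2 * 100)))

    def test_certain_weekend_missingness_hits_exactly_2015_weekends(self):
        missing_weekends = MissingnessParams(
            weekend_missing_prob=1.0, edge_gap_days=(0, 0), random_gap_rate=0.0
        )
        series = generate_pollen_year(NOISELESS, 2015, missing_weekends, seed=1)
        missing_days = (np.flatnonzero(np.isnan(series.values)) + 1).tolist()
        assert missing_days == weekend_days_oracle(2015)
        assert len(missing_days) == 104

    def test_same_seed_reproduces_bit_identical_series(self):
        params = PollenModelParams()
        a = generate_pollen_year(params, 2015, MissingnessParams(), seed=42)
        b = generate_pollen_year(params, 2015, MissingnessParams(), seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_parameter_validation_names_the_field(self):
        with pytest.raises(ValueError, match="noise_cv"):
            PollenModelParams(noise_cv=-0.1)
        with pytest.raises(ValueError, match="peak1_width_days"):
            PollenModelParams(peak1_width_days=0)
        with pytest.raises(ValueError, match="invalid year"):
            generate_pollen_year(NOISELESS, 0, NO_MISSING, seed=0)

    def test_leap_year_generates_feb29(self):
        series = generate_pollen_year(NOISELESS, 2016, NO_MISSING, seed=0)
        assert series.values.size == 366

    def test_noiseless_argmax_is_peak1_day(self):
        params = PollenModelParams(noise_cv=0.0)
        series = generate_pollen_year(params, 2015, NO_MISSING, seed=0)
        assert int(np.argmax(series.values)) + 1 == int(params.peak1_day)


class TestSearchGeneration:
    def test_identity_coupling_is_monotone_transform_of_pollen(self):
        pollen = generate_pollen_year(PollenModelParams(noise_cv=0.3), 2015,
                                      NO_MISSING, seed=5)
        params = SearchModelParams(
            lag_days=0, response_exponent=1.0, baseline_rate=0.0,
            noise_cv=0.0, censor_threshold=0.0, n_replicates=1,
            replicate_noise_cv=0.0,
        )
        (rep,) = generate_search_year(pollen, params, seed=0)
        assert np.nanmax(rep.values) == 100.0
        # Integer quantisation ties low-valued days; on untied days the
        # reported series is a monotone transform of pollen.
        values, counts = np.unique(rep.values, return_counts=True)
        untied = np.isin(rep.values, values[counts == 1])
        rho = stats.spearmanr(rep.values[untied], pollen.values[untied]).statistic
        assert rho >= 0.99

    def test_full_censoring_yields_flagged_all_zero_series(self):
        pollen = generate_pollen_year(NOISELESS, 2015, NO_MISSING, seed=0)
        params = SearchModelParams(
            noise_cv=0.0, replicate_noise_cv=0.0, n_replicates=2,
            censor_threshold=1e9,
        )
        for rep in generate_search_year(pollen, params, seed=0):
            assert np.all(rep.values == 0)
            assert "all_censored" in rep.flags

    def test_censoring_at_latent_median_zeroes_exactly_the_lower_half(self):
        pollen = generate_pollen_year(PollenModelParams(noise_cv=0.0), 2015,
                                      NO_MISSING, seed=0)
        base = SearchModelParams(
            lag_days=0, response_exponent=0.7, baseline_rate=10.0,
            noise_cv=0.0, n_replicates=1, replicate_noise_cv=0.0,
            censor_threshold=0.0,
        )
        # Latent series recomputed independently from the closed form.
        latent = base.baseline_rate + pollen.values**base.response_exponent
        threshold = float(np.percentile(latent, 50))
        params = dataclasses.replace(base, censor_threshold=threshold)
        (rep,) = generate_search_year(pollen, params, seed=0)
        np.testing.assert_array_equal(rep.values == 0, latent < threshold)

    def test_raising_threshold_never_decreases_zero_days(self):
        pollen = generate_pollen_year(PollenModelParams(), 2015, NO_MISSING, seed=9)
        previous = -1
        for threshold in (0.0, 5.0, 12.0, 30.0, 80.0):
            params = SearchModelParams(censor_threshold=threshold, n_replicates=1)
            (rep,) = generate_search_year(pollen, params, seed=7)
            zeros = int(np.sum(rep.values == 0))
            assert zeros >= previous
            previous = zeros

    def test_every_noncensored_replicate_peaks_at_100(self):
        pollen = generate_pollen_year(PollenModelParams(), 2015,
                                      MissingnessParams(), seed=3)
        for rep in generate_search_year(pollen, SearchModelParams(), seed=3):
            assert np.nanmax(rep.values) == 100.0
            assert np.all(rep.values == np.round(rep.values))


class TestPanelGeneration:
    def test_fixed_seed_panel_is_bit_identical_on_rerun(self):
        spec = PanelSpec(n_site_years=3, seed=17)
        first = generate_panel(spec)
        second = generate_panel(spec)
        assert len(first) == 3
        for (s1, r1), (s2, r2) in zip(first, second):
            np.testing.assert_array_equal(s1.series.values, s2.series.values)
            np.testing.assert_array_equal(r1.averaged.values, r2.averaged.values)
            assert r1.tv_homes == r2.tv_homes

    def test_clean_spec_gives_perfect_rank_agreement(self):
        spec = PanelSpec(
            n_site_years=2, seed=5,
            pollen=dataclasses.replace(PollenModelParams(), noise_cv=0.0),
            search=SearchModelParams(
                noise_cv=0.0, replicate_noise_cv=0.0, n_replicates=1,
                censor_threshold=0.0, response_exponent=1.0, baseline_rate=0.0,
            ),
            missingness=NO_MISSING,
            amplitude_jitter_cv=0.0,
        )
        for station, region in generate_panel(spec):
            search = region.averaged.values
            values, counts = np.unique(search, return_counts=True)
            joint = ~np.isnan(station.series.values) & np.isin(
                search, values[counts == 1]
            )
            rho = stats.spearmanr(
                station.series.values[joint], search[joint]
            ).statistic
            assert rho > 0.999

    def test_zero_fraction_declines_with_log_tv_homes(self):
        spec = PanelSpec(
            n_site_years=40, seed=23,
            censor_tv_homes_ref=3e5,
            tv_homes_range=(1e4, 1e7),  # three orders of magnitude
        )
        zeros, log_tv = [], []
        for station, region in generate_panel(spec):
            zeros.append(float(np.mean(region.averaged.values == 0)))
            log_tv.append(np.log(region.tv_homes))
        slope, _, _ = ols_closed_form(log_tv, zeros)
        assert slope < 0
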