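import numpy as np
import pytest

from pollenproxy.association import (
    associate_pair,
    compare_groups,
    peak_snr,
    quartile_stratify,
    screen_covariate,
    spearman_rho,
    AssociationResult,
)
from pollenproxy.series import SEARCH
from pollenproxy.synthetic import PanelSpec, generate_panel

from conftest import make_series
from oracles import ols_closed_form, pooled_t_stat, spearman_brute


def _pair(x_values, y_values, kind="transformed"):
    x = make_series(kind=kind, day_values={i + 1: v for i, v in enumerate(x_values)})
    y = make_series(kind=kind, day_values={i + 1: v for i, v in enumerate(y_values)})
    return x, y


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self, rng):
        base = rng.gamma(2, 10, 10)
        x, y = _pair(base, 2 * base + 1)
        rho, n = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_reversed_order_gives_minus_one(self, rng):
        base = np.sort(rng.gamma(2, 10, 12))
        x, y = _pair(base, base[::-1])
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_average_rank_formula(self):
        xv = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0]
        yv = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 7.0, 7.0]
        x, y = _pair(xv, yv)
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(spearman_brute(xv, yv), abs=1e-12)

    def test_pairwise_complete_uses_jointly_observed_days_only(self):
        x = make_series(day_values={1: 1.0, 2: 2.0, 3: np.nan, 4: 4.0, 5: 5.0})
        y = make_series(day_values={1: 2.0, 2: 4.0, 3: 6.0, 4: np.nan, 5: 10.0})
        rho, n = spearman_rho(x, y)
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_fewer_than_three_days_flagged(self):
        x = make_series(day_values={1: 1.0, 2: 2.0})
        y = make_series(day_values={1: 1.0, 2: 2.0})
        rho, n = spearman_rho(x, y)
        assert rho is None and n == 2

    @pytest.mark.parametrize(
        "transform", [np.log1p, lambda v: 3 * v + 2, lambda v: v**3]
    )
    def test_invariant_under_strictly_increasing_transforms(self, rng, transform):
        base = rng.gamma(2.0, 10.0, 40)
        noise = base + rng.normal(0, 5, 40)
        x, y = _pair(base, noise)
        rho_raw, _ = spearman_rho(x, y)
        xt, yt = _pair(transform(base), noise)
        rho_t, _ = spearman_rho(xt, yt)
        assert rho_t == pytest.approx(rho_raw, abs=1e-12)


class TestPeakSnr:
    def test_constant_and_linear_series_score_zero(self):
        assert peak_snr(make_series(fill=7.0, kind=SEARCH)) == pytest.approx(0.0)
        linear = make_series(
            kind=SEARCH,
            day_values={d: d / 4.0 for d in range(1, 182)},
        )
        assert peak_snr(linear, scale="raw") == pytest.approx(0.0, abs=1e-8)

    def test_isolated_peak_matches_brute_force_lowess_residual(self):
        from oracles import brute_lowess

        values = {d: 0.0 for d in range(1, 182)}
        for d in range(88, 98):
            values[d] = 100.0
        series = make_series(kind=SEARCH, day_values=values)
        days = np.arange(1, 182, dtype=float)
        raw = np.array([values[d] for d in range(1, 182)])
        expected = np.mean(np.abs(raw - brute_lowess(days, raw, 0.8)))
        assert peak_snr(series, scale="raw") == pytest.approx(expected, abs=1e-8)

    def test_scales_linearly_with_amplitude_on_raw_scale(self, rng):
        values = rng.gamma(2, 5, 120)
        a = make_series(day_values={i + 1: v for i, v in enumerate(values)})
        b = make_series(day_values={i + 1: 3 * v for i, v in enumerate(values)})
        assert peak_snr(b, scale="raw") == pytest.approx(
            3 * peak_snr(a, scale="raw"), rel=1e-9
        )


class TestQuartiles:
    @staticmethod
    def _results(covariates, rhos=None):
        rhos = rhos if rhos is not None else [0.5] * len(covariates)
        return [
            AssociationResult(
                site_year_id=f"S{i}", rho=r, n_days=100,
                pct_gt_zero_days=c, pct_gt_missing_days=0.0, peak_snr=c,
            )
            for i, (c, r) in enumerate(zip(covariates, rhos))
        ]

    def test_linear_interpolation_cutoffs_and_balanced_groups(self):
        results = self._results([1, 2, 3, 4, 5, 6, 7, 8])
        annotated, summary = quartile_stratify(results, "pct_missing")
        assert summary.cutoffs == pytest.approx((2.75, 4.5, 6.25))
        counts = {q: 0 for q in (1, 2, 3, 4)}
        for r in annotated:
            counts[r.quartile_by_missing] += 1
        assert counts == {1: 2, 2: 2, 3: 2, 4: 2}

    def test_equal_covariates_degenerate_warning(self):
        annotated, summary = quartile_stratify(self._results([5.0] * 6))
        assert summary.degenerate_cutoffs
        assert all(r.quartile_by_missing == 1 for r in annotated)

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        results = self._results(rng.uniform(0, 50, 37),
                                rhos=rng.uniform(-1, 1, 37))
        annotated, summary = quartile_stratify(results, "peak_snr")
        assert sorted(summary.assignments) == sorted(r.site_year_id
                                                     for r in annotated)
        assert all(r.quartile_by_snr in (1, 2, 3, 4) for r in annotated)

    def test_too_few_site_years_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            quartile_stratify(self._results([1, 2, 3]))


class TestGroupComparison:
    def test_identical_groups_t_zero_p_one(self, rng):
        a = rng.normal(0.5, 0.1, 12)
        result = compare_groups(a, a.copy())
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_shifted_zero_variance_groups_are_certain(self):
        result = compare_groups([0.2] * 5, [1.2] * 5)
        assert result.p_value < 1e-12 or np.isnan(result.p_value)
        assert abs(result.statistic) > 1e6 or np.isinf(result.statistic)

    def test_matches_textbook_pooled_formula(self, rng):
        a = rng.normal(0.6, 0.2, 15)
        b = rng.normal(0.4, 0.25, 11)
        result = compare_groups(a, b)
        assert result.statistic == pytest.approx(pooled_t_stat(a, b), rel=1e-10)


class TestCovariateScreen:
    def test_perfect_line_and_orthogonal_data(self, rng):
        x = np.arange(20.0)
        screen = screen_covariate(x, 2 * x - 3)
        assert screen.r_squared == pytest.approx(1.0)
        assert screen.slope == pytest.approx(2.0)
        y = np.tile([1.0, -1.0], 10)
        assert abs(screen_covariate(x, y).slope) < 0.02

    def test_matches_closed_form_least_squares(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 1.5 * x + rng.normal(0, 2, 30)
        screen = screen_covariate(x, y)
        slope, intercept, r2 = ols_closed_form(x, y)
        assert screen.slope == pytest.approx(slope, rel=1e-10)
        assert screen.intercept == pytest.approx(intercept, rel=1e-10)
        assert screen.r_squared == pytest.approx(r2, rel=1e-10)
        assert screen.slope_ci[0] < slope < screen.slope_ci[1]

    def test_log_transform_of_covariate(self, rng):
        tv_homes = rng.uniform(1e4, 1e6, 25)
        y = -5 * np.log(tv_homes) + rng.normal(0, 1, 25)
        screen = screen_covariate(tv_homes, y, log_x=True)
        assert screen.slope == pytest.approx(-5.0, abs=0.5)


def test_associate_pair_reports_covariates_and_rho():
    spec = PanelSpec(n_site_years=1, seed=99)
    ((station, region),) = generate_panel(spec)
    result = associate_pair(station, region)
    assert result.rho is not None and -1 <= result.rho <= 1
    assert result.n_days >= 3
    assert 0 <= result.pct_gt_zero_days <= 100
    assert result.peak_snr >= 0
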