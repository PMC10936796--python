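"""Weighted quantiles, ECDFs and the niche indices built on them."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trawlniche import (
    interval_width,
    niche_summary,
    occupancy_interval,
    seasonal_mean_compare,
    steno_index,
    thermal_bias,
    weighted_ecdf,
    weighted_quantile,
)
from trawlniche.errors import (
    ComputationError,
    ConfigError,
    DegenerateWeightError,
    InsufficientDataError,
    NoCatchError,
)

from conftest import stations_from


class TestWeightedQuantile:
    @pytest.mark.parametrize(
        "values,weights,p,expected",
        [
            ([1, 2, 3], [1, 1, 1], 0.5, 2.0),
            ([10, 20], [3, 1], 0.5, 10.0),  # median of expanded [10,10,10,20]
            ([10, 20], [3, 1], 0.75, 12.5),  # h = 3.25 on 4 expanded points
            ([5], [2], 0.3, 5.0),
            ([1, 2, 3], [1, 1, 1], 0.0, 1.0),
            ([1, 2, 3], [1, 1, 1], 1.0, 3.0),
        ],
    )
    def test_known_values(self, values, weights, p, expected):
        assert weighted_quantile(values, weights, p) == pytest.approx(expected)

    def test_all_zero_weights_error(self):
        with pytest.raises(DegenerateWeightError):
            weighted_quantile([1, 2], [0, 0], 0.5)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            weighted_quantile([1, 2, 3], [1, 1], 0.5)

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            weighted_quantile([1, 2], [1, 1], 1.5)

    def test_zero_weight_values_ignored(self):
        assert weighted_quantile([1, 99, 3], [1, 0, 1], 1.0) == 3.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50).map(lambda x: round(x, 2)),
                st.integers(0, 20),
            ),
            min_size=1,
            max_size=12,
        ).filter(lambda d: sum(w for _, w in d) > 0 and sum(w for _, w in d) <= 200),
        p=st.floats(0, 1),
    )
    def test_expansion_oracle_equivalence(self, data, p):
        """Integer weights: equals np.quantile of the expanded vector."""
        values = [v for v, _ in data]
        weights = [w for _, w in data]
        expanded = np.repeat(values, weights)
        assert weighted_quantile(values, weights, p) == pytest.approx(
            float(np.quantile(expanded, p)), abs=1e-9
        )

    def test_continuous_in_p(self):
        values, weights = [1.0, 4.0, 9.0], [2, 3, 1]
        ps = np.linspace(0, 1, 101)
        qs = weighted_quantile(values, weights, ps)
        assert np.all(np.diff(qs) >= -1e-12)  # monotone
        assert np.max(np.abs(np.diff(qs))) < 1.0  # no jumps at this resolution


class TestWeightedECDF:
    def test_bounds(self):
        f = weighted_ecdf([1.0, 2.0, 3.0], [1, 2, 1])
        assert f(3.0) == 1.0
        assert f(0.5) == 0.0

    def test_unit_weights_match_empirical_cdf(self):
        f = weighted_ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        assert f(2.5) == pytest.approx(2 / 3)
        assert f(1.0) == pytest.approx(1 / 3)

    def test_right_continuity_and_monotonicity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        w = rng.integers(1, 5, size=40)
        f = weighted_ecdf(v, w)
        xs = np.sort(np.concatenate([v, v - 1e-12, v + 1e-12]))
        ys = f(xs)
        assert np.all(np.diff(ys) >= 0)
        assert np.all((ys >= 0) & (ys <= 1))

    def test_ties_merged(self):
        f = weighted_ecdf([2.0, 2.0, 5.0], [1, 1, 2])
        assert f.support.tolist() == [2.0, 5.0]
        assert f(2.0) == pytest.approx(0.5)

    def test_quantile_cdf_sandwich_on_support(self):
        # interpolated quantiles sit between a support point and its successor
        v = np.array([1.0, 3.0, 7.0, 9.0])
        w = np.array([2, 1, 4, 3])
        f = weighted_ecdf(v, w)
        for i, x in enumerate(v):
            q = weighted_quantile(v, w, f(x))
            upper = v[i + 1] if i + 1 < len(v) else x
            assert x - 1e-9 <= q <= upper + 1e-9


class TestThermalBias:
    def test_concentrated_catch(self):
        st_ = stations_from([4, 5, 6, 7, 8], [0, 0, 0, 0, 10])
        assert thermal_bias(st_) == pytest.approx(2.0)  # 8 − 6

    def test_uniform_catch_is_zero(self):
        st_ = stations_from([4, 5, 6, 7, 8], [3, 3, 3, 3, 3])
        assert thermal_bias(st_) == pytest.approx(0.0)

    def test_catch_at_median_station_is_zero(self):
        st_ = stations_from([4, 5, 6, 7, 8], [0, 0, 9, 0, 0])
        assert thermal_bias(st_) == pytest.approx(0.0)

    def test_zero_total_catch_errors(self):
        with pytest.raises(NoCatchError):
            thermal_bias(stations_from([4, 5], [0, 0]))

    def test_missing_temperatures_excluded_everywhere(self):
        st_ = stations_from([4, 5, 6, 7, 8, None], [0, 0, 0, 0, 10, 50])
        assert thermal_bias(st_) == pytest.approx(2.0)

    def test_translation_shifts_nothing(self):
        temps = [3.0, 5.0, 6.5, 8.0]
        catches = [1, 0, 4, 2]
        base = thermal_bias(stations_from(temps, catches))
        shifted = thermal_bias(stations_from([t + 3.2 for t in temps], catches))
        assert shifted == pytest.approx(base)


class TestStenoIndex:
    def test_point_mass_is_zero(self):
        st_ = stations_from([4, 5, 6], [0, 7, 0])
        assert steno_index(st_) == pytest.approx(0.0)

    def test_unit_catches_1_to_100(self):
        st_ = stations_from(list(range(1, 101)), [1] * 100)
        assert steno_index(st_) == pytest.approx(95.05 - 5.95)

    def test_translation_invariance(self):
        temps = [2.0, 4.0, 6.0, 8.0]
        catches = [1, 5, 3, 2]
        a = steno_index(stations_from(temps, catches))
        b = steno_index(stations_from([t - 7.7 for t in temps], catches))
        assert a == pytest.approx(b)

    def test_scale_equivariance(self):
        temps = [2.0, 4.0, 6.0, 8.0]
        catches = [1, 5, 3, 2]
        a = steno_index(stations_from(temps, catches))
        b = steno_index(stations_from([3.0 * t for t in temps], catches))
        assert b == pytest.approx(3.0 * a)

    def test_closed_form_on_synthetic_survey(self, catch_stations):
        # product-of-Gaussians: catch-weighted T ~ N(7.150, 0.6352)
        assert steno_index(catch_stations) == pytest.approx(3.2897 * 0.6352, abs=0.12)


class TestOccupancyInterval:
    def test_point_mass(self):
        st_ = stations_from([7.0], [5])
        assert occupancy_interval(st_, "temperature") == (7.0, 7.0)

    def test_full_range_at_0_1(self):
        st_ = stations_from([3.0, 5.0, 9.0], [1, 1, 1])
        assert occupancy_interval(st_, "temperature", 0.0, 1.0) == (3.0, 9.0)

    def test_unit_weights_1_to_100(self):
        st_ = stations_from(list(range(1, 101)), [1] * 100)
        lo, hi = occupancy_interval(st_, "temperature", 0.05, 0.95, weighted=True)
        assert (lo, hi) == (pytest.approx(5.95), pytest.approx(95.05))

    def test_unweighted_ignores_catches(self):
        st_ = stations_from([1.0, 2.0, 3.0], [0, 0, 99])
        lo, hi = occupancy_interval(st_, "temperature", 0.0, 1.0, weighted=False)
        assert (lo, hi) == (1.0, 3.0)

    def test_depth_variable(self):
        st_ = stations_from([7.0] * 3, [1, 1, 1])
        for i, d in enumerate([100.0, 400.0, 900.0]):
            st_[i].depth = d
        assert occupancy_interval(st_, "depth", 0.0, 1.0) == (100.0, 900.0)

    def test_bad_percentiles(self):
        st_ = stations_from([7.0], [5])
        with pytest.raises(ConfigError):
            occupancy_interval(st_, "temperature", 0.9, 0.1)

    def test_unknown_variable(self):
        with pytest.raises(ConfigError):
            occupancy_interval(stations_from([7.0], [1]), "salinity")


class TestIntervalWidth:
    @pytest.mark.parametrize(
        "interval,width",
        [((315.0, 546.0), 231.0), ((241.0, 461.0), 220.0), ((5.0, 5.0), 0.0)],
    )
    def test_widths(self, interval, width):
        assert interval_width(interval) == width

    def test_inverted_interval_errors(self):
        with pytest.raises(ComputationError):
            interval_width((10.0, 5.0))


class TestSeasonalMeanCompare:
    def test_identical_groups_f_zero(self):
        f, p, df = seasonal_mean_compare([1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0)
        assert df == (1, 4)

    def test_hand_computed_example(self):
        f, p, df = seasonal_mean_compare([1, 2, 3], [4, 5, 6])
        assert f == pytest.approx(13.5)
        assert df == (1, 4)

    def test_f_equals_t_squared(self):
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        a = rng.normal(6.9, 0.4, size=30)
        b = rng.normal(7.1, 0.5, size=45)
        f, p, _ = seasonal_mean_compare(a, b)
        t, pt = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(pt, abs=1e-12)

    def test_insufficient_group(self):
        with pytest.raises(InsufficientDataError):
            seasonal_mean_compare([1.0], [2.0, 3.0])


class TestNicheSummary:
    def test_uniform_catch_tb_zero(self):
        st_ = stations_from([4, 5, 6, 7, 8], [2, 2, 2, 2, 2])
        s = niche_summary(st_, "temperature")
        assert s.tb == pytest.approx(0.0)
        assert s.n_stations == 5 and s.total_catch == 10

    def test_zero_catch_errors(self):
        with pytest.raises(NoCatchError):
            niche_summary(stations_from([4, 5], [0, 0]), "temperature")

    def test_depth_summary_has_no_tb(self):
        st_ = stations_from([7.0] * 4, [1, 2, 3, 4])
        s = niche_summary(st_, "depth")
        assert s.tb is None
        assert s.steno >= 0

    def test_records_percentile_convention(self):
        st_ = stations_from([4, 5, 6, 7, 8], [1, 1, 1, 1, 1])
        s = niche_summary(st_, "temperature", lo_p=0.10, hi_p=0.90)
        assert s.percentiles == (0.10, 0.90)

    def test_season_filter_restricts_scope(self):
        spring = stations_from([5.0, 6.0], [1, 1], survey="spring")
        autumn = stations_from([8.0, 9.0], [1, 1])
        s = niche_summary(spring + autumn, "temperature", season="spring")
        assert s.n_stations == 2
        assert s.interval[1] <= 6.0

    def test_synthetic_survey_matches_closed_form(self, catch_stations):
        s = niche_summary(catch_stations, "temperature")
        assert s.tb == pytest.approx(1.46, abs=0.12)
        assert s.steno == pytest.approx(2.09, abs=0.12)
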