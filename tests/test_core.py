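import numpy as np
import pytest

from conftest import make_series
from slopefill import (
    Gap,
    InsufficientDataError,
    NonUniformSpacingError,
    SlopeStats,
    TimeSeries,
    UnboundedGapError,
    constrain_gap,
    find_gaps,
    first_order_slopes,
    impute,
    linear_fill,
    percentile_threshold,
)
from slopefill.core import unbounded_runs

NA = float("nan")


class TestTimeSeries:
    def test_rejects_non_unit_integer_spacing(self):
        with pytest.raises(NonUniformSpacingError):
            TimeSeries(np.array([0, 1, 3]), np.array([1.0, 2.0, 3.0]))

    def test_rejects_non_daily_dates(self):
        times = np.array(["2024-01-01", "2024-01-02", "2024-01-04"], dtype="datetime64[D]")
        with pytest.raises(NonUniformSpacingError, match="2024-01-04"):
            TimeSeries(times, np.array([1.0, 2.0, 3.0]))

    def test_rejects_short_and_infinite(self):
        with pytest.raises(ValueError):
            make_series([1.0])
        with pytest.raises(ValueError):
            make_series([1.0, np.inf])

    def test_warns_on_negative_concentrations(self):
        with pytest.warns(UserWarning, match="negative"):
            make_series([1.0, -2.0, 3.0])

    def test_date_index_round_numbers(self):
        s = TimeSeries.from_values([1.0, NA, 3.0], start="2024-01-05")
        assert s.n_missing == 1
        assert s.times[0] == np.datetime64("2024-01-05")


class TestFirstOrderSlopes:
    @pytest.mark.parametrize(
        "values, diffs",
        [
            ([3, 5, 2], [2, -3]),
            ([7, 7, 7], [0, 0]),
            ([1, NA, 4, 6], [2]),  # the 1->4 pair spans a gap and is excluded
        ],
    )
    def test_adjacent_observed_pairs(self, values, diffs):
        stats = first_order_slopes(make_series(values))
        np.testing.assert_array_equal(stats.diffs, diffs)
        np.testing.assert_array_equal(stats.abs_slopes, np.abs(diffs))
        assert stats.n_pairs == len(diffs)

    def test_no_adjacent_pair_errors(self):
        with pytest.raises(InsufficientDataError, match="insufficient observed"):
            first_order_slopes(make_series([1, NA, 2, NA, 3]))


class TestPercentileThreshold:
    def test_linear_interpolation_convention(self):
        stats = SlopeStats(diffs=np.arange(0, 101, 10.0),
                           abs_slopes=np.arange(0, 101, 10.0), n_pairs=11)
        assert percentile_threshold(stats, 95).tau == pytest.approx(95.0)

    @pytest.mark.parametrize("p", [1, 50, 95, 100])
    def test_degenerate_distributions(self, p):
        flat = SlopeStats(np.full(4, 5.0), np.full(4, 5.0), 4)
        assert percentile_threshold(flat, p).tau == 5.0
        single = SlopeStats(np.array([7.0]), np.array([7.0]), 1)
        assert percentile_threshold(single, p).tau == 7.0

    def test_input_validation(self):
        stats = SlopeStats(np.array([1.0]), np.array([1.0]), 1)
        for p in (0, -5, 101):
            with pytest.raises(ValueError):
                percentile_threshold(stats, p)
        empty = SlopeStats(np.array([]), np.array([]), 0)
        with pytest.raises(InsufficientDataError):
            percentile_threshold(empty, 95)


class TestGaps:
    def test_interior_run_becomes_one_gap(self):
        gaps = find_gaps(make_series([1, NA, NA, 4, 5]))
        assert len(gaps) == 1
        g = gaps[0]
        assert (g.left_index, g.right_index) == (0, 3)
        assert (g.left_value, g.right_value) == (1.0, 4.0)
        np.testing.assert_array_equal(g.missing_indices, [1, 2])

    def test_complete_series_has_no_gaps(self):
        assert find_gaps(make_series([1, 2, 3])) == []

    def test_leading_run_is_unbounded_not_a_gap(self):
        s = make_series([NA, 2, NA, 3])
        gaps = find_gaps(s)
        assert len(gaps) == 1
        assert (gaps[0].left_index, gaps[0].right_index) == (1, 3)
        leading, trailing = unbounded_runs(s)
        np.testing.assert_array_equal(leading, [0])
        assert trailing.size == 0


class TestLinearFill:
    @pytest.mark.parametrize(
        "gap, expected",
        [
            (Gap(0, 4, 0.0, 40.0, np.array([1, 2, 3])), [10.0, 20.0, 30.0]),
            (Gap(0, 2, 5.0, 5.0, np.array([1])), [5.0]),
            (Gap(0, 2, 20.0, 0.0, np.array([1])), [10.0]),
        ],
    )
    def test_chord_values(self, gap, expected):
        np.testing.assert_allclose(linear_fill(gap), expected)

    def test_malformed_gap(self):
        with pytest.raises(ValueError, match="malformed"):
            linear_fill(Gap(3, 3, 1.0, 2.0, np.array([], dtype=int)))


class TestConstrainGap:
    def test_sequential_clipping_propagates(self):
        gap = Gap(0, 4, 0.0, 40.0, np.array([1, 2, 3]))
        finals, records = constrain_gap(gap, [10.0, 20.0, 30.0], tau=6.0)
        np.testing.assert_allclose(finals, [6.0, 12.0, 18.0])
        assert all(r.clipped for r in records)
        assert [r.applied_slope for r in records] == [6.0, 6.0, 6.0]

    def test_descending_clip_keeps_direction(self):
        gap = Gap(0, 2, 20.0, 0.0, np.array([1]))
        finals, records = constrain_gap(gap, [10.0], tau=4.0)
        np.testing.assert_allclose(finals, [16.0])
        assert records[0].clipped and records[0].applied_slope == -4.0

    def test_inactive_constraint_returns_linear(self):
        gap = Gap(0, 4, 0.0, 40.0, np.array([1, 2, 3]))
        linear = np.array([10.0, 20.0, 30.0])
        finals, records = constrain_gap(gap, linear, tau=10.0)
        np.testing.assert_array_equal(finals, linear)
        assert not any(r.clipped for r in records)


class TestImpute:
    def test_complete_series_is_identity(self):
        s = make_series([3, 1, 4, 1, 5])
        result = impute(s, 95)
        np.testing.assert_array_equal(result.series.values, s.values)
        assert result.clip_log == []

    def test_composed_clipping_example(self):
        # observed slopes are all ±6, so tau = 6 at any percentile
        s = make_series([0, 6, 12, 6, 0, NA, NA, NA, 40])
        result = impute(s, 95)
        assert result.threshold.tau == 6.0
        np.testing.assert_allclose(result.series.values[5:8], [6.0, 12.0, 18.0])
        # reconnection from 18 up to the observed 40 exceeds tau by 16
        assert result.gap_diagnostics[0].reconnection_excess == pytest.approx(16.0)

    def test_reduces_to_linear_when_tau_dominates(self):
        # all observed slopes equal the chord slope, so nothing clips
        values = np.arange(30, dtype=float)
        holed = values.copy()
        holed[[5, 6, 17]] = NA
        result = impute(make_series(holed), 100)
        np.testing.assert_array_equal(result.series.values, values)
        assert result.n_clipped == 0

    def test_observed_positions_untouched(self, short_volatile_series):
        v = short_volatile_series.values.copy()
        v[10:13] = NA
        v[50] = NA
        result = impute(TimeSeries(short_volatile_series.times, v), 95)
        obs = ~np.isnan(v)
        np.testing.assert_array_equal(
            result.series.values[obs], short_volatile_series.values[obs]
        )

    def test_unbounded_run_policies(self):
        s = make_series([NA, 2, NA, 8, 5])
        with pytest.raises(UnboundedGapError):
            impute(s, 95)
        result = impute(s, 95, boundary="nearest")
        assert result.series.values[0] == 2.0
        boundary_records = [r for r in result.clip_log if r.boundary]
        assert [r.index for r in boundary_records] == [0]

    def test_operation_count_linear_in_length(self):
        for n in (50, 200, 800):
            values = np.arange(n, dtype=float)
            values[n // 3: n // 3 + 5] = NA
            result = impute(make_series(values), 95)
            assert result.n_operations <= 2 * n
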