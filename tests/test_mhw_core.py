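"""Climatology construction, interpolation, detection and classification."""

import numpy as np
import pandas as pd
import pytest

from helpers import brute_doy_curves, brute_event_segments
from mhwkelp import (
    BaselineCoverageError,
    CadenceError,
    Climatology,
    DegenerateClimatologyError,
    GridCell,
    GridSeries,
    MHWEvent,
    TemperatureSeries,
    build_climatology,
    categorize_event,
    detect_events,
    interpolate_to_daily,
    spatial_extent,
)


def _daily(start, values, **kw):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return TemperatureSeries.from_arrays(dates, values, **kw)


# ---------------------------------------------------------------- climatology


class TestBuildClimatology:
    def test_constant_series_gives_flat_curves(self):
        s = _daily("1971-01-01", np.full(29 * 365 + 7, 10.0))
        clim = build_climatology(s, "1971-01-01", "1999-12-31")
        assert np.allclose(clim.doy_mean, 10.0)
        assert np.allclose(clim.doy_p90, 10.0)

    def test_percentile_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        dates = pd.date_range("1971-01-01", "1999-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        values = 10 + 4 * np.sin(2 * np.pi * doy / 365.25) + rng.normal(0, 1.5, len(dates))
        s = TemperatureSeries.from_arrays(dates, values)
        clim = build_climatology(s, "1971-01-01", "1999-12-31",
                                 window_half_width=5, smoothing_width=31)
        mean_o, p90_o = brute_doy_curves(dates, values, 5, 31)
        assert np.allclose(clim.doy_mean, mean_o, atol=1e-10)
        assert np.allclose(clim.doy_p90, p90_o, atol=1e-10)

    def test_percentile_matches_oracle_without_smoothing(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("1971-01-01", "1999-12-31", freq="D")
        values = 8 + rng.normal(0, 2, len(dates))
        s = TemperatureSeries.from_arrays(dates, values)
        clim = build_climatology(s, "1971-01-01", "1999-12-31",
                                 window_half_width=2, smoothing_width=1)
        mean_o, p90_o = brute_doy_curves(dates, values, 2, 1)
        assert np.allclose(clim.doy_p90, p90_o, atol=1e-10)

    def test_known_pooled_window_values(self):
        # every doy window pools the same five values -> p90 by sorted interpolation
        vals = np.array([8.0, 9.0, 10.0, 11.0, 12.0])
        dates = pd.date_range("1971-01-01", "1999-12-31", freq="D")
        rng = np.random.default_rng(0)
        values = rng.permuted(np.resize(vals, len(dates)))
        s = TemperatureSeries.from_arrays(dates, values)
        # wide window so each pooled set is a large balanced sample of {8..12}
        clim = build_climatology(s, "1971-01-01", "1999-12-31",
                                 window_half_width=30, smoothing_width=1)
        pooled = np.sort(np.resize(vals, 61 * 29))
        h = 0.9 * (len(pooled) - 1)
        expected = pooled[int(h)] + (h - int(h)) * (pooled[int(h) + 1] - pooled[int(h)])
        assert abs(np.median(clim.doy_p90) - expected) < 0.15

    def test_sinusoid_mean_tracks_within_smoothing_bias(self):
        dates = pd.date_range("1971-01-01", "1999-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        values = 10 + 5 * np.sin(2 * np.pi * doy / 365.25)
        s = TemperatureSeries.from_arrays(dates, values)
        clim = build_climatology(s, "1971-01-01", "1999-12-31")
        curve = 10 + 5 * np.sin(2 * np.pi * np.arange(1, 367) / 365.25)
        # smoothing bias of a 31-day average of a sinusoid is < 2% of amplitude
        assert np.max(np.abs(clim.doy_mean - curve)) < 0.15
        # p90 - mean bounded by max slope x pooling-window width
        max_slope = 5 * 2 * np.pi / 365.25
        assert np.max(clim.doy_p90 - clim.doy_mean) <= max_slope * 11

    def test_insufficient_baseline_raises(self):
        s = _daily("1990-01-01", np.full(5 * 365, 10.0))
        with pytest.raises(BaselineCoverageError, match="year-equivalents"):
            build_climatology(s, "1990-01-01", "1994-12-31")

    def test_weekly_input_directed_to_interpolation(self):
        dates = pd.date_range("1971-01-01", periods=2000, freq="7D")
        s = TemperatureSeries.from_arrays(dates, np.full(2000, 10.0))
        with pytest.raises(CadenceError, match="interpolate_to_daily"):
            build_climatology(s, "1971-01-01", "1999-12-31")

    def test_feb29_interpolated_between_neighbours(self):
        rng = np.random.default_rng(7)
        dates = pd.date_range("1971-01-01", "1999-12-31", freq="D")
        values = 10 + rng.normal(0, 1, len(dates))
        clim = build_climatology(
            TemperatureSeries.from_arrays(dates, values),
            "1971-01-01", "1999-12-31", smoothing_width=1,
        )
        assert clim.doy_mean[59] == pytest.approx(0.5 * (clim.doy_mean[58] + clim.doy_mean[60]))

    def test_invariant_p90_at_least_mean(self):
        with pytest.raises(ValueError, match="doy_p90"):
            Climatology.flat(10.0, 12.0).__class__(
                baseline_start=pd.Timestamp("1971-01-01"),
                baseline_end=pd.Timestamp("1999-12-31"),
                doy_mean=np.full(366, 10.0),
                doy_p90=np.full(366, 9.0),
                window_half_width_days=5,
                smoothing_width_days=31,
            )


# -------------------------------------------------------------- interpolation


class TestInterpolateToDaily:
    def test_weekly_linear_ramp(self):
        dates = pd.to_datetime(["2018-06-01", "2018-06-08"])
        s = TemperatureSeries.from_arrays(dates, [10.0, 17.0])
        out = interpolate_to_daily(s)
        assert out.interpolated and out.cadence == "daily"
        assert np.allclose(out.values, np.arange(10.0, 18.0))

    def test_single_observation_unchanged(self):
        s = TemperatureSeries.from_arrays(pd.to_datetime(["2018-06-01"]), [12.0])
        out = interpolate_to_daily(s)
        assert len(out) == 1 and out.values[0] == 12.0

    def test_long_gap_left_missing(self):
        dates = pd.to_datetime(["2018-06-01", "2018-07-31"])  # 60 days apart
        s = TemperatureSeries.from_arrays(dates, [10.0, 12.0], cadence="weekly")
        out = interpolate_to_daily(s, max_gap_days=30)
        assert np.isfinite(out.values[0]) and np.isfinite(out.values[-1])
        assert np.isnan(out.values[1:-1]).all()

    def test_no_extrapolation(self):
        dates = pd.to_datetime(["2018-06-01", "2018-06-08", "2018-06-15"])
        out = interpolate_to_daily(TemperatureSeries.from_arrays(dates, [10, 11, 12.0]))
        assert out.dates[0] == dates[0] and out.dates[-1] == dates[-1]


# ------------------------------------------------------------------ detection


class TestDetectEvents:
    def test_rectangular_pulse(self, flat_clim, make_series):
        s = make_series(overrides={i: 15.0 for i in range(100, 110)})
        events = detect_events(s, flat_clim)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration_days == 10
        assert ev.max_intensity == pytest.approx(5.0)
        assert ev.mean_intensity == pytest.approx(5.0)
        assert ev.cumulative_intensity == pytest.approx(50.0)
        assert ev.max_temperature == pytest.approx(15.0)
        assert ev.start_date == s.dates[100] and ev.end_date == s.dates[109]

    def test_four_day_run_below_min_duration(self, flat_clim, make_series):
        s = make_series(overrides={i: 15.0 for i in range(100, 104)})
        assert detect_events(s, flat_clim) == []

    def test_gap_joining_two_runs(self, flat_clim, make_series):
        hot = {i: 15.0 for i in list(range(100, 106)) + list(range(108, 114))}
        s = make_series(overrides=hot)
        events = detect_events(s, flat_clim, max_gap=2)
        assert len(events) == 1
        assert events[0].duration_days == 14
        segs = brute_event_segments(s.values, np.full(365, 12.0))
        assert segs == [(100, 113)]

    def test_gap_beyond_max_not_joined(self, flat_clim, make_series):
        hot = {i: 15.0 for i in list(range(100, 106)) + list(range(109, 115))}
        s = make_series(overrides=hot)
        events = detect_events(s, flat_clim, max_gap=2)
        assert [e.duration_days for e in events] == [6, 6]

    def test_missing_day_breaks_run_and_forbids_join(self, flat_clim, make_series):
        hot = {i: 15.0 for i in range(100, 112)}
        hot[105] = np.nan
        s = make_series(overrides=hot)
        events = detect_events(s, flat_clim)
        # 100-104 qualifies (5 d), 106-111 qualifies (6 d), NaN gap forbids joining
        assert [e.duration_days for e in events] == [5, 6]

    def test_tie_with_threshold_is_not_exceedance(self, flat_clim, make_series):
        s = make_series(overrides={i: 12.0 for i in range(100, 120)})
        assert detect_events(s, flat_clim) == []

    def test_deterministic_and_chronological(self, flat_clim):
        rng = np.random.default_rng(11)
        s = _daily("2018-01-01", 10 + rng.normal(0, 2.5, 730))
        e1 = detect_events(s, flat_clim)
        e2 = detect_events(s, flat_clim)
        assert e1 == e2
        starts = [e.start_date for e in e1]
        assert starts == sorted(starts)

    def test_matches_brute_force_on_random_series(self, flat_clim):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = 10 + rng.normal(0, 2.5, 400)
            values[rng.integers(0, 400, 15)] = np.nan
            s = _daily("2017-03-01", values)
            events = detect_events(s, flat_clim)
            segs = brute_event_segments(values, np.full(400, 12.0))
            assert [(e.start_date, e.end_date) for e in events] == [
                (s.dates[a], s.dates[b]) for a, b in segs
            ]

    def test_threshold_monotonicity(self, make_series):
        rng = np.random.default_rng(9)
        s = _daily("2018-01-01", 10 + rng.normal(0, 2.5, 365))
        day_count = []
        for p90 in (11.0, 12.0, 13.0):
            evs = detect_events(s, Climatology.flat(10.0, p90))
            day_count.append(sum(e.duration_days for e in evs))
        assert day_count[0] >= day_count[1] >= day_count[2]


# ------------------------------------------------------------- categorization


class TestCategorizeEvent:
    def _event(self, max_intensity, peak="2018-07-15"):
        p = pd.Timestamp(peak)
        return MHWEvent(
            start_date=p - pd.Timedelta(days=3),
            end_date=p + pd.Timedelta(days=3),
            peak_date=p,
            duration_days=7,
            max_intensity=max_intensity,
            mean_intensity=max_intensity / 2,
            cumulative_intensity=3.5 * max_intensity,
            max_temperature=10 + max_intensity,
        )

    def test_ratio_two_and_a_half_is_category_three(self, flat_clim):
        assert categorize_event(self._event(5.0), flat_clim) == 3

    def test_vanishing_ratio_is_category_one(self, flat_clim):
        assert categorize_event(self._event(1e-4), flat_clim) == 1

    def test_exact_bin_edge_assigned_to_lower_bin(self, flat_clim):
        assert categorize_event(self._event(2.0), flat_clim) == 1
        assert categorize_event(self._event(4.0), flat_clim) == 2

    def test_overflow_clipped_to_four(self, flat_clim):
        ev = self._event(11.0)  # ratio 5.5
        assert categorize_event(ev, flat_clim) == 4
        assert ev.category_overflow

    def test_degenerate_climatology_raises(self):
        clim = Climatology.flat(10.0, 10.0)
        with pytest.raises(DegenerateClimatologyError):
            categorize_event(self._event(3.0), clim)


# ------------------------------------------------------------- spatial extent


def _grid_cell(cell_id, km, hot_days=(), year=2018):
    dates = pd.date_range(f"{year}-01-01", periods=365, freq="D")
    values = np.full(365, 10.0)
    for d in hot_days:
        values[d] = 15.0
    series = TemperatureSeries.from_arrays(dates, values, site_id=cell_id)
    return GridCell(cell_id=cell_id, coastline_km=km, series=series,
                    clim=Climatology.flat(10.0, 12.0))


class TestSpatialExtent:
    def test_no_cell_in_event(self):
        grid = GridSeries(cells=[_grid_cell("a", 100.0), _grid_cell("b", 100.0)])
        assert spatial_extent(grid, "2018-07-15").km == 0.0

    def test_additivity_over_cells(self):
        hot = tuple(range(190, 200))
        grid = GridSeries(cells=[
            _grid_cell("a", 100.0, hot), _grid_cell("b", 100.0, hot),
            _grid_cell("c", 100.0), _grid_cell("d", 100.0),
        ])
        ext = spatial_extent(grid, "2018-07-15")  # doy index 195 is inside hot
        assert ext.km == 200.0
        assert sorted(ext.cells_in_event) == ["a", "b"]

    def test_construction_oracle_and_missing_coverage(self):
        hot = tuple(range(190, 200))
        cells = [_grid_cell(f"c{i}", 50.0, hot if i in (1, 3, 4) else ()) for i in range(6)]
        cells[5].series.data.iloc[:] = np.nan
        grid = GridSeries(cells=cells)
        ext = spatial_extent(grid, "2018-07-15")
        assert ext.km == 150.0
        assert ext.cells_missing == ["c5"]


# ------------------------------------------------------------ event invariants


def test_events_satisfy_invariants_on_synthetic_series(flat_clim):
    rng = np.random.default_rng(21)
    noise = np.zeros(1095)
    for i in range(1, 1095):  # red noise so multi-day exceedance runs occur
        noise[i] = 0.8 * noise[i - 1] + rng.normal(0, 1.5)
    s = _daily("2016-01-01", 10 + noise)
    events = detect_events(s, flat_clim)
    assert events, "fixture should produce events"
    for ev in events:
        assert ev.duration_days >= 5
        assert ev.start_date <= ev.peak_date <= ev.end_date
        assert ev.cumulative_intensity == pytest.approx(ev.mean_intensity * ev.duration_days)
        assert ev.max_intensity >= ev.mean_intensity > 0
        assert ev.category in (1, 2, 3, 4)
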