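"""Marine heatwave (MHW) detection from daily temperature records.

A marine heatwave is a period of more than five consecutive days on which
sea temperature exceeds the day-of-year 90th-percentile threshold of a
fixed-baseline climatology.  Severity categories I-IV scale the peak
anomaly (relative to the climatological mean) by the gap between the
climatological 90th percentile and the climatological mean at the event
peak.

The module provides:

* :class:`TemperatureSeries` — a dated scalar temperature record at a
  site/depth, the raw input to everything downstream;
* :func:`build_climatology` — day-of-year mean and 90th-percentile
  threshold curves pooled over a calendar-day window and circularly
  smoothed;
* :func:`interpolate_to_daily` — linear interpolation of weekly or
  irregular records onto the daily grid (gap-limited, no extrapolation);
* :func:`detect_events` — run-length exceedance detection with
  gap-joining, returning :class:`MHWEvent` objects;
* :func:`categorize_event` — the I-IV severity classification;
* :func:`spatial_extent` — coastline length inside an event on a given
  date, summed over the cells of a :class:`GridSeries`.

Day-of-year handling uses a 366-slot axis (leap-year layout).  Feb 29
observations are excluded from climatology pooling; the Feb 29 slot of
both curves is filled by interpolating between Feb 28 and Mar 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TemperatureSeries",
    "Climatology",
    "MHWEvent",
    "GridCell",
    "GridSeries",
    "SpatialExtent",
    "CadenceError",
    "BaselineCoverageError",
    "DegenerateClimatologyError",
    "build_climatology",
    "interpolate_to_daily",
    "detect_events",
    "categorize_event",
    "spatial_extent",
]


class CadenceError(ValueError):
    """Raised when a series has the wrong sampling cadence for an operation."""


class BaselineCoverageError(ValueError):
    """Raised when the baseline window holds too little non-missing data."""


class DegenerateClimatologyError(ValueError):
    """Raised when the 90th-percentile threshold does not exceed the mean."""


# --------------------------------------------------------------------------
# Temperature series container
# --------------------------------------------------------------------------


@dataclass
class TemperatureSeries:
    """A dated temperature record at a single site and depth.

    Parameters
    ----------
    site_id:
        Free-text station identifier.
    depth_m:
        Logger depth in metres.
    data:
        ``pd.Series`` of temperature (°C) indexed by calendar date
        (time-of-day is dropped); NaN marks missing days.
    cadence:
        ``"daily"``, ``"weekly"`` or ``"irregular"``.
    interpolated:
        True when values were produced by :func:`interpolate_to_daily`.
    """

    site_id: str
    depth_m: float
    data: pd.Series
    cadence: str = "daily"
    interpolated: bool = False

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.data.index).normalize()
        values = np.asarray(self.data, dtype=float)
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate date in series: {dup.date()}")
        finite_ok = np.isfinite(values) | np.isnan(values)
        if not finite_ok.all():
            raise ValueError("temperature values must be finite or NaN")
        self.data = pd.Series(values, index=idx, name="temperature")

    @classmethod
    def from_arrays(
        cls,
        dates: Sequence,
        values: Sequence[float],
        site_id: str = "site",
        depth_m: float = 1.0,
        cadence: str | None = None,
        interpolated: bool = False,
    ) -> "TemperatureSeries":
        data = pd.Series(np.asarray(values, float), index=pd.DatetimeIndex(dates))
        if cadence is None:
            cadence = infer_cadence(data.index)
        return cls(site_id, depth_m, data, cadence, interpolated)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def infer_cadence(dates: pd.DatetimeIndex) -> str:
    """Infer cadence from the median spacing of observation dates."""
    if len(dates) < 2:
        return "daily"
    spacing = np.median(np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int))
    if spacing <= 1:
        return "daily"
    if spacing <= 8:
        return "weekly"
    return "irregular"


# --------------------------------------------------------------------------
# Day-of-year axis helpers (366-slot leap layout)
# --------------------------------------------------------------------------

_FEB29_SLOT = 59  # 0-based index of Feb 29 on the 366-slot axis


def leap_doy_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """0-based index of each date on the 366-slot (leap-year) axis."""
    doy = dates.dayofyear.to_numpy()
    leap = np.asarray(dates.is_leap_year)
    return doy - 1 + ((~leap) & (doy > 59)).astype(int)


def _doy365_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """0-based index on the 365-slot axis; Feb 29 maps to -1 (excluded)."""
    doy = dates.dayofyear.to_numpy()
    leap = np.asarray(dates.is_leap_year)
    idx = doy - 1 - (leap & (doy > 60)).astype(int)
    idx[leap & (doy == 60)] = -1
    return idx


def _expand_365_to_366(curve365: np.ndarray) -> np.ndarray:
    out = np.empty(366)
    out[:_FEB29_SLOT] = curve365[:_FEB29_SLOT]
    out[_FEB29_SLOT] = 0.5 * (curve365[58] + curve365[59])
    out[_FEB29_SLOT + 1 :] = curve365[_FEB29_SLOT:]
    return out


# --------------------------------------------------------------------------
# Climatology
# --------------------------------------------------------------------------


@dataclass
class Climatology:
    """Day-of-year mean and 90th-percentile curves from a baseline period.

    Both curves are length 366 (leap layout), finite and periodic: the
    calendar-day pooling window and the moving-average smoother wrap
    across the year boundary.
    """

    baseline_start: pd.Timestamp
    baseline_end: pd.Timestamp
    doy_mean: np.ndarray
    doy_p90: np.ndarray
    window_half_width_days: int
    smoothing_width_days: int

    def __post_init__(self) -> None:
        self.doy_mean = np.asarray(self.doy_mean, float)
        self.doy_p90 = np.asarray(self.doy_p90, float)
        if self.doy_mean.shape != (366,) or self.doy_p90.shape != (366,):
            raise ValueError("climatology curves must have length 366")
        if not (np.isfinite(self.doy_mean).all() and np.isfinite(self.doy_p90).all()):
            raise ValueError("climatology curves must be finite")
        if np.any(self.doy_p90 < self.doy_mean - 1e-9):
            raise ValueError("doy_p90 must be >= doy_mean on every day of year")

    @classmethod
    def flat(cls, mean: float, p90: float) -> "Climatology":
        """Constant curves; convenient for constructed fixtures."""
        return cls(
            baseline_start=pd.Timestamp("1971-01-01"),
            baseline_end=pd.Timestamp("1999-12-31"),
            doy_mean=np.full(366, float(mean)),
            doy_p90=np.full(366, float(p90)),
            window_half_width_days=0,
            smoothing_width_days=1,
        )

    def mean_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.doy_mean[leap_doy_index(dates)]

    def threshold_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.doy_p90[leap_doy_index(dates)]


def build_climatology(
    series: TemperatureSeries,
    baseline_start,
    baseline_end,
    window_half_width: int = 5,
    smoothing_width: int = 31,
    min_years: float = 20.0,
) -> Climatology:
    """Pool baseline values in a wrapped calendar-day window, take the mean
    and 90th percentile per day of year, and smooth both curves with a
    circular moving average.

    Percentiles use linear interpolation between order statistics.  The
    baseline must contribute at least ``min_years`` year-equivalents of
    non-missing daily data (default 20).
    """
    if series.cadence != "daily" or infer_cadence(series.dates) != "daily":
        raise CadenceError(
            "build_climatology requires a daily series; pass weekly or irregular "
            "records through interpolate_to_daily first"
        )
    start = pd.Timestamp(baseline_start)
    end = pd.Timestamp(baseline_end)
    base = series.data.loc[start:end].dropna()
    year_equiv = len(base) / 365.25
    if year_equiv < min_years:
        raise BaselineCoverageError(
            f"baseline {start.date()}..{end.date()} holds {year_equiv:.1f} "
            f"year-equivalents of non-missing data; at least {min_years:g} required"
        )

    idx365 = _doy365_index(base.index)
    keep = idx365 >= 0  # Feb 29 observations excluded from pooling
    vals = base.to_numpy()[keep]
    idx365 = idx365[keep]

    by_doy: list[np.ndarray] = [vals[idx365 == d] for d in range(365)]
    w = int(window_half_width)
    mean365 = np.empty(365)
    p90_365 = np.empty(365)
    for d in range(365):
        pooled = np.concatenate([by_doy[(d + k) % 365] for k in range(-w, w + 1)])
        if pooled.size == 0:
            raise BaselineCoverageError(
                f"no baseline observations within ±{w} days of day-of-year {d + 1}"
            )
        mean365[d] = pooled.mean()
        p90_365[d] = np.percentile(pooled, 90, method="linear")

    s = int(smoothing_width)
    if s > 1:
        mean365 = uniform_filter1d(mean365, size=s, mode="wrap")
        p90_365 = uniform_filter1d(p90_365, size=s, mode="wrap")

    return Climatology(
        baseline_start=start,
        baseline_end=end,
        doy_mean=_expand_365_to_366(mean365),
        doy_p90=_expand_365_to_366(np.maximum(p90_365, mean365)),
        window_half_width_days=w,
        smoothing_width_days=s,
    )


# --------------------------------------------------------------------------
# Interpolation of weekly records
# --------------------------------------------------------------------------


def interpolate_to_daily(
    series: TemperatureSeries, max_gap_days: int = 30
) -> TemperatureSeries:
    """Linearly interpolate a weekly/irregular record onto the daily grid.

    No extrapolation beyond the first/last observation; spans between
    observations more than ``max_gap_days`` apart are left missing rather
    than bridged.  The output is flagged ``interpolated``.
    """
    obs = series.data.dropna()
    if len(obs) <= 1:
        return replace(series, interpolated=series.interpolated)
    spacing = np.median(np.diff(obs.index.to_numpy()).astype("timedelta64[D]").astype(int))
    # a single long gap between two observations is governed by max_gap_days;
    # the spacing precondition targets systematically sparse records
    if spacing > 14 and len(obs) > 2:
        raise CadenceError(
            f"median observation spacing {spacing:.0f} d exceeds 14 d; "
            "record too sparse to interpolate to daily"
        )
    full = pd.date_range(obs.index[0], obs.index[-1], freq="D")
    daily = obs.reindex(full).interpolate(method="time")
    gaps = np.diff(obs.index.to_numpy()).astype("timedelta64[D]").astype(int)
    for i, g in enumerate(gaps):
        if g > max_gap_days:
            lo, hi = obs.index[i], obs.index[i + 1]
            daily[(daily.index > lo) & (daily.index < hi)] = np.nan
    return TemperatureSeries(
        site_id=series.site_id,
        depth_m=series.depth_m,
        data=daily,
        cadence="daily",
        interpolated=True,
    )


# --------------------------------------------------------------------------
# Event detection and classification
# --------------------------------------------------------------------------


@dataclass
class MHWEvent:
    """A detected marine heatwave.

    Intensities are anomalies relative to the climatological mean
    (``doy_mean``), in °C; ``cumulative_intensity`` is their sum over the
    event days (degree-days).  ``category`` is the I-IV severity class
    (None when the climatology is degenerate at the peak).
    """

    start_date: pd.Timestamp
    end_date: pd.Timestamp
    peak_date: pd.Timestamp
    duration_days: int
    max_intensity: float
    mean_intensity: float
    cumulative_intensity: float
    max_temperature: float
    category: int | None = None
    category_overflow: bool = False

    def __post_init__(self) -> None:
        if not (self.start_date <= self.peak_date <= self.end_date):
            raise ValueError("event must satisfy start <= peak <= end")
        if self.duration_days != (self.end_date - self.start_date).days + 1:
            raise ValueError("duration_days inconsistent with start/end dates")


def _exceedance_runs(exceed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    runs: list[tuple[int, int]] = []
    n = len(exceed)
    i = 0
    while i < n:
        if exceed[i]:
            j = i
            while j + 1 < n and exceed[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_events(
    series: TemperatureSeries,
    clim: Climatology,
    min_duration: int = 5,
    max_gap: int = 2,
) -> list[MHWEvent]:
    """Detect marine heatwaves: maximal runs of days with T strictly above
    the day-of-year 90th-percentile threshold, of length >= ``min_duration``.

    Two qualifying runs separated by at most ``max_gap`` non-missing
    below-threshold days are joined into one event; the joined gap days
    count toward duration and intensity.  Missing days break runs and
    prevent joining.  Events are returned in chronological order.
    """
    if len(series) == 0:
        return []
    if series.cadence != "daily":
        raise CadenceError("detect_events requires a daily series")
    full = pd.date_range(series.dates[0], series.dates[-1], freq="D")
    t = series.data.reindex(full).to_numpy()
    thr = clim.threshold_for(full)
    mu = clim.mean_for(full)
    valid = np.isfinite(t)
    exceed = valid & (t > thr)

    qualifying = [
        (a, b) for a, b in _exceedance_runs(exceed) if b - a + 1 >= min_duration
    ]
    merged: list[list[int]] = []
    for a, b in qualifying:
        if (
            merged
            and a - merged[-1][1] - 1 <= max_gap
            and valid[merged[-1][1] + 1 : a].all()
        ):
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events: list[MHWEvent] = []
    for a, b in merged:
        anom = t[a : b + 1] - mu[a : b + 1]
        peak = a + int(np.argmax(anom))
        ev = MHWEvent(
            start_date=full[a],
            end_date=full[b],
            peak_date=full[peak],
            duration_days=b - a + 1,
            max_intensity=float(anom.max()),
            mean_intensity=float(anom.mean()),
            cumulative_intensity=float(anom.sum()),
            max_temperature=float(np.nanmax(t[a : b + 1])),
        )
        try:
            categorize_event(ev, clim)
        except DegenerateClimatologyError:
            ev.category = None
        events.append(ev)
    return events


def categorize_event(event: MHWEvent, clim: Climatology) -> int:
    """Severity category I-IV from the ratio of the peak anomaly to the
    climatological gap (p90 - mean) at the peak date.

    Bin edges are closed above (ratio exactly 1.0 -> category I); ratios
    above 4 are clipped to category IV with ``category_overflow`` set.
    """
    dates = pd.DatetimeIndex([event.peak_date])
    delta = float(clim.threshold_for(dates)[0] - clim.mean_for(dates)[0])
    if delta <= 0:
        raise DegenerateClimatologyError(
            f"p90 - mean = {delta:.3g} at {event.peak_date.date()}; "
            "cannot classify against a degenerate climatology"
        )
    ratio = event.max_intensity / delta
    category = min(4, max(1, math.ceil(ratio)))
    event.category = category
    event.category_overflow = ratio > 4
    return category


# --------------------------------------------------------------------------
# Spatial extent over a grid
# --------------------------------------------------------------------------


@dataclass
class GridCell:
    cell_id: str
    coastline_km: float
    series: TemperatureSeries
    clim: Climatology | None = None
    _events: list[MHWEvent] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coastline_km < 0:
            raise ValueError("coastline_km must be >= 0")


@dataclass
class GridSeries:
    """Per-cell temperature series and climatologies with coastline lengths,
    used to measure the linear coastal extent of an event."""

    cells: list[GridCell]

    def build_climatologies(self, baseline_start, baseline_end, **kwargs) -> None:
        for cell in self.cells:
            cell.clim = build_climatology(
                cell.series, baseline_start, baseline_end, **kwargs
            )
            cell._events = None


@dataclass
class SpatialExtent:
    km: float
    cells_in_event: list[str]
    cells_missing: list[str]

    def __float__(self) -> float:
        return self.km


def spatial_extent(grid: GridSeries, date) -> SpatialExtent:
    """Sum of coastline length over grid cells inside a detected MHW on
    ``date``.  Cells missing data on that date are excluded and listed in
    the coverage report."""
    day = pd.Timestamp(date).normalize()
    km = 0.0
    in_event: list[str] = []
    missing: list[str] = []
    for cell in grid.cells:
        if cell.clim is None:
            raise ValueError(f"cell {cell.cell_id}: climatology not built")
        val = cell.series.data.get(day, np.nan)
        if not np.isfinite(val):
            missing.append(cell.cell_id)
            continue
        if cell._events is None:
            cell._events = detect_events(cell.series, cell.clim)
        if any(ev.start_date <= day <= ev.end_date for ev in cell._events):
            km += cell.coastline_km
            in_event.append(cell.cell_id)
    return SpatialExtent(km=km, cells_in_event=in_event, cells_missing=missing)
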