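"""Ecological exceedance metrics derived from detected marine heatwaves.

Turns event lists into the year-indexed series used by the trend models:
event frequency, cumulative intensity (degree-days), and mean duration of
events whose maximum temperature crossed a species mortality threshold.
Also provides the winter seasonal mask and between-period change summaries.

Mortality thresholds are the arithmetic mean of stage-specific thermal
tolerance limits (adult and early life stages of *Saccharina latissima*),
rounded to one decimal.  Threshold crossing uses >= (an event that equals
the threshold counts), whereas heatwave detection itself uses strict
exceedance of the climatological percentile — the two thresholds are
different objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mhw_core import MHWEvent, TemperatureSeries

__all__ = [
    "AnnualMetricSeries",
    "MortalityThreshold",
    "PeriodChange",
    "seasonal_mask",
    "mortality_threshold",
    "threshold_crossing_events",
    "annual_event_frequency",
    "annual_cumulative_intensity",
    "annual_crossing_duration",
    "period_change",
]


@dataclass
class AnnualMetricSeries:
    """A year-indexed metric (one value per year, NaN where undefined)."""

    years: np.ndarray
    values: np.ndarray
    metric_name: str
    units: str

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.values = np.asarray(self.values, float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must align")
        if len(np.unique(self.years)) != len(self.years):
            raise ValueError("one value per year required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, self.metric_name: self.values})

    def loc(self, year: int) -> float:
        return float(self.values[np.searchsorted(self.years, year)])


@dataclass(frozen=True)
class MortalityThreshold:
    """Species mortality threshold: mean of stage tolerances, 1 decimal."""

    region: str
    stage_tolerances: tuple
    threshold: float


@dataclass(frozen=True)
class PeriodChange:
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    ratio_pct: float | None  # None when mean1 == 0 (undefined)


def seasonal_mask(
    series: TemperatureSeries,
    exclude_start: tuple[int, int] = (1, 1),
    exclude_end: tuple[int, int] = (4, 1),
) -> TemperatureSeries:
    """Mask the winter period each year: values on the half-open month-day
    interval [exclude_start, exclude_end) are set missing.

    With the defaults, Jan 1 - Mar 31 are masked and Apr 1 is kept, so the
    analysis is restricted to the warm season when temperatures approach
    kelp tolerance limits.  A wrapped interval (start > end) is supported.
    """
    if len(series) == 0:
        return replace(series)
    mth = series.dates.month.to_numpy()
    day = series.dates.day.to_numpy()
    key = mth * 100 + day
    k0 = exclude_start[0] * 100 + exclude_start[1]
    k1 = exclude_end[0] * 100 + exclude_end[1]
    if k0 <= k1:
        mask = (key >= k0) & (key < k1)
    else:  # wrapped across the new year
        mask = (key >= k0) | (key < k1)
    data = series.data.copy()
    data[mask] = np.nan
    return replace(series, data=data)


def mortality_threshold(
    stage_tolerances: Sequence[float],
    region: str = "",
    literal: float | None = None,
) -> MortalityThreshold:
    """Mortality threshold as the mean of stage-specific tolerance limits,
    rounded to one decimal.  ``literal`` overrides the computed value (for
    reproducing a published threshold that differs from the plain mean)."""
    tol = tuple(float(t) for t in stage_tolerances)
    if not tol:
        raise ValueError("stage_tolerances must be non-empty")
    thr = float(literal) if literal is not None else round(float(np.mean(tol)), 1)
    return MortalityThreshold(region=region, stage_tolerances=tol, threshold=thr)


def threshold_crossing_events(
    events: Iterable[MHWEvent], thr: MortalityThreshold
) -> list[MHWEvent]:
    """Events whose maximum temperature equaled or exceeded the threshold."""
    return [ev for ev in events if ev.max_temperature >= thr.threshold]


def _year_axis(year_range: tuple[int, int]) -> np.ndarray:
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y1 < y0:
        raise ValueError("year_range must be (first, last) with first <= last")
    return np.arange(y0, y1 + 1)


def _event_year(ev: MHWEvent) -> int:
    # boundary-spanning events belong to the year they start in
    return int(ev.start_date.year)


def annual_event_frequency(
    events: Iterable[MHWEvent], year_range: tuple[int, int]
) -> AnnualMetricSeries:
    """Count of events per year (zero-filled), by start-date year."""
    years = _year_axis(year_range)
    counts = np.zeros(len(years))
    for ev in events:
        y = _event_year(ev)
        if not years[0] <= y <= years[-1]:
            raise ValueError(f"event starting {ev.start_date.date()} outside year_range")
        counts[y - years[0]] += 1
    return AnnualMetricSeries(years, counts, "event_frequency", "events yr^-1")


def annual_cumulative_intensity(
    events: Iterable[MHWEvent], year_range: tuple[int, int]
) -> AnnualMetricSeries:
    """Summed cumulative intensity of all events in each year (degree-days)."""
    years = _year_axis(year_range)
    total = np.zeros(len(years))
    for ev in events:
        y = _event_year(ev)
        if not years[0] <= y <= years[-1]:
            raise ValueError(f"event starting {ev.start_date.date()} outside year_range")
        total[y - years[0]] += ev.cumulative_intensity
    return AnnualMetricSeries(years, total, "cumulative_intensity", "degree-days yr^-1")


def annual_crossing_duration(
    events: Iterable[MHWEvent],
    thr: MortalityThreshold,
    year_range: tuple[int, int],
) -> AnnualMetricSeries:
    """Mean duration of threshold-crossing events per year.

    Years with no crossing event are missing (NaN), not zero: the metric is
    the duration of events that crossed the mortality threshold, which is
    undefined in a year without such events.
    """
    years = _year_axis(year_range)
    sums = np.zeros(len(years))
    counts = np.zeros(len(years))
    for ev in threshold_crossing_events(events, thr):
        y = _event_year(ev)
        if not years[0] <= y <= years[-1]:
            raise ValueError(f"event starting {ev.start_date.date()} outside year_range")
        sums[y - years[0]] += ev.duration_days
        counts[y - years[0]] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AnnualMetricSeries(years, mean, "crossing_duration", "days")


def period_change(
    metric: AnnualMetricSeries,
    period1: tuple[int, int],
    period2: tuple[int, int],
) -> PeriodChange:
    """Mean ± SD of the metric in two year windows and the percent ratio
    100 × mean(period2) / mean(period1).  SDs are sample SDs across years.
    A zero first-period mean leaves the ratio undefined (None)."""

    def window(period):
        lo, hi = int(period[0]), int(period[1])
        sel = (metric.years >= lo) & (metric.years <= hi)
        vals = metric.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"period {lo}-{hi} holds no values of {metric.metric_name}")
        return vals

    v1, v2 = window(period1), window(period2)
    m1, m2 = float(v1.mean()), float(v2.mean())
    sd1 = float(v1.std(ddof=1)) if v1.size > 1 else 0.0
    sd2 = float(v2.std(ddof=1)) if v2.size > 1 else 0.0
    ratio = None if m1 == 0 else 100.0 * m2 / m1
    return PeriodChange(mean1=m1, sd1=sd1, mean2=m2, sd2=sd2, ratio_pct=ratio)
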