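# mhwkelp

Marine heatwaves (MHWs) — periods of more than five consecutive days with sea
temperature above the day-of-year 90th-percentile climatological threshold —
are a leading driver of mortality in warm range-edge kelp forests
(*Saccharina latissima* in the Skagerrak and southern New England). `mhwkelp`
is a tested, reusable pipeline for the analysis chain that links long-term
coastal temperature records to kelp mortality:

* **Climatology and detection** (`mhw_core`): day-of-year mean m(d) and
  90th-percentile threshold T90(d) from a fixed baseline period (default
  1971-01-01 to 1999-12-31), pooled over a ±5-day calendar window and
  smoothed with a 31-day circular moving average; run-length detection of
  events with T(t) > T90(d), minimum duration 5 days, joining across gaps of
  ≤ 2 days; severity categories I–IV from
  ceil(max intensity / (T90 − m)) at the event peak; linear coastal extent of
  an event over a gridded SST field.
* **Exceedance metrics** (`exceedance_metrics`): winter masking
  (Jan 1 – Apr 1, half-open), species mortality thresholds as the mean of
  stage-specific thermal tolerances (e.g. mean(20, 20, 19) = 19.7 °C),
  annual event frequency, annual cumulative intensity Σᵢ (Tᵢ − m) in
  degree-days, mean duration of threshold-crossing events, and
  between-period change (mean ± SD per period, percent ratio).
* **Trend models** (`trend_models`): OLS with the classical slope t-test,
  *exact* quantile regression (pinball loss via linear programming, default
  τ = 0.90), and a cubic P-spline smoother with GCV-chosen penalty for
  nonlinear trends.
* **Field analysis** (`field_analysis`): percent cover from photo-quadrat
  point counts, blade growth from hole-punch displacement, distal erosion,
  tagged/transplant mortality rates, monthly-rate conversion, Pearson tests,
  and a profiled-ML random-intercept model comparing mortality on turf- vs
  kelp-dominated reefs with region as the random effect.
* **Synthetic data** (`synthetic_data`): daily temperature series
  (seasonal cycle + warming trend + AR(1) noise), injected heatwave
  anomalies with an exact ground-truth ledger, logistic
  threshold-exceedance kelp mortality, and annual cover dynamics — so every
  stage is testable without downloads.
* **I/O and CLI** (`io_interface`, `cli`): CSV station/event/metric tables,
  NetCDF SST grids, YAML run configuration, and a `mhwkelp` command with
  `simulate`, `climatology`, `detect`, `metrics`, `trends` and `field`
  subcommands.

## Worked example

```python
import numpy as np
from mhwkelp import *

# a 60-year synthetic record with increasingly frequent injected heatwaves
cfg = TempGenConfig(start_year=1959, n_years=60, seed=11)
base = simulate_temperature(cfg, site_id="flodevigen-like")
sched = make_event_schedule(1959, 60, base_rate=1.0, rate_trend=0.04, seed=12)
series, ledger = inject_events(base, sched)

clim = build_climatology(series, "1971-01-01", "1999-12-31")
events = detect_events(seasonal_mask(series), clim)
thr = mortality_threshold([20, 20, 19], region="S_Norway")
crossing = threshold_crossing_events(events, thr)
print(len(events), thr.threshold, len(crossing))

freq = annual_event_frequency(events, (1959, 2018))
fit = linear_trend(freq.years, freq.values)
print(f"frequency slope {fit.slope:.4f} ev/yr^2, R2={fit.r_squared:.2f}, p={fit.p_value:.3g}")

cum = annual_cumulative_intensity(events, (1959, 2018))
pc = period_change(cum, (1959, 1988), (1989, 2018))
print(f"{pc.mean1:.1f}±{pc.sd1:.0f} -> {pc.mean2:.1f}±{pc.sd2:.0f} degree-days ({pc.ratio_pct:.0f}%)")
```

prints

```
134 19.7 72
frequency slope 0.0769 ev/yr^2, R2=0.53, p=3.23e-11
40.0±46 -> 145.1±90 degree-days (363%)
```

i.e. 134 detected heatwaves of which 72 reached the 19.7 °C kelp mortality
threshold, a significantly increasing annual event frequency, and a
roughly 3.6-fold rise in annual cumulative heatwave intensity between the
two 30-year halves of the record — the synthetic world is built to behave
like a warming warm-edge site, and the pipeline quantifies it.

The same pipeline runs from the shell:

```sh
mhwkelp simulate --start-year 1971 --n-years 48 --seed 5 --out series.csv
mhwkelp detect --input series.csv --baseline 1971-01-01:1999-12-31 \
               --mask-winter --out events.csv
mhwkelp metrics --events events.csv --years 1971:2018 --threshold 19.7 \
                --out-prefix metric
mhwkelp trends --metric metric_frequency.csv --out trend.json
```

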