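# Methods

## Heatwave definition and climatology

A marine heatwave is a run of more than five consecutive days on which the
daily temperature strictly exceeds the day-of-year 90th-percentile
threshold of a fixed-baseline climatology. The climatology pools all
baseline observations whose day-of-year lies within ±`window_half_width`
days of each target day (wrapping the calendar), takes the mean and the
90th percentile (linear interpolation between order statistics), and
smooths both curves with a circular moving average of width
`smoothing_width`. Defaults are `window_half_width = 5` (an 11-day pooling
window) and `smoothing_width = 31` days, the standard choices of the
widely used heatwave-detection framework; both are exposed in
configuration because published analyses do not always state them, and
quantities such as the duration of a specific event can depend on them.

The baseline defaults to 1 January 1971 – 31 December 1999. Note this span
is 29 calendar years even where a "30-year baseline" is the nominal
convention; the dates are taken literally. `build_climatology` requires at
least 20 year-equivalents of non-missing daily baseline data and raises an
error naming the deficit otherwise.

Day-of-year handling uses a 366-slot (leap-year) axis. Feb 29
observations are excluded from pooling; the Feb 29 slot of each curve is
filled by interpolating between Feb 28 and Mar 1. Exceedance is strict
(T > threshold): a day exactly on the threshold does not count. Missing
days break exceedance runs; interpolation of sparse records happens only
explicitly, before detection, via `interpolate_to_daily` (linear in time,
no extrapolation, gaps longer than `max_gap_days = 30` left missing; the
median-spacing precondition applies to records with three or more
observations, while a single long gap between two observations is governed
by the max-gap rule alone).

Two qualifying runs separated by at most `max_gap = 2` non-missing
below-threshold days are joined into one event, and the joined gap days
count toward duration and intensity. Intensities are anomalies relative to
the climatological *mean* (not the threshold), so cumulative intensity is
the integral of the anomaly in degree-days.

### Severity categories

Category = ceil(max intensity / Δ) clipped to [1, 4], where Δ = threshold −
mean at the event peak date. Bin edges are closed above (a ratio of exactly
1.0 is category I, matching the "I = 0–1" convention); ratios above 4 are
reported as category IV with an overflow flag. A degenerate climatology
(Δ ≤ 0, possible only for noise-free constructions where the percentile
equals the mean) makes classification impossible: `categorize_event`
raises, and `detect_events` records `category = None` for such events so
noise-free exact-recovery fixtures remain usable.

## Exceedance metrics

The winter period is masked on the half-open interval
[Jan 1, Apr 1) — Apr 1 itself is kept — because the analysis targets the
warm season when temperatures approach kelp tolerance limits. Species
mortality thresholds are the arithmetic mean of stage-specific thermal
tolerance limits rounded to one decimal (northeast Atlantic adults/early
stages (20, 20, 19) °C → 19.7 °C; northwest Atlantic (20, 25, 23) °C →
22.7 °C); a `literal` override exists for reproducing a published value
that differs from the plain mean. Threshold crossing uses ≥ (an event
whose maximum temperature equals the threshold counts), deliberately
different from the strict > of detection: the two thresholds are different
objects.

Events are assigned to the calendar year of their start date. Years with
no crossing event contribute *missing* (not zero) to the mean crossing
duration, since the metric is the duration of events that crossed the
threshold. Between-period change reports per-period mean ± sample SD and
the percent ratio of the means; a zero first-period mean leaves the ratio
undefined rather than infinite.

## Trend models

* `linear_trend`: OLS; R² = 1 − SSE/SST; two-sided slope p-value from the
  t distribution with n − 2 df. An optional AR(1) correction inflates the
  slope SE by the Bartlett factor √((1+ρ)/(1−ρ)) from the lag-1 residual
  autocorrelation; it is off by default to match the plain linear-model
  convention common in this literature.
* `quantile_trend`: exact minimization of the check loss
  Σ ρ_τ(y − a − bx) through its linear-programming formulation (HiGHS),
  with a secondary LP and a vertex-snapping step so that among
  loss-optimal lines the one with minimal |b| is returned. An optimal line
  passes through at least two data points, which makes the fit checkable
  against exhaustive pair enumeration at small n. No distributional
  standard error is attached to quantile fits (`slope_se`, `p_value`,
  `r_squared` are None); the point estimate, not inference, is what the
  upper-tail duration trend uses. The sample-size precondition is 10
  points for tail quantiles (|τ − 0.5| > 0.25) and 5 otherwise.
* `spline_smooth`: a penalized cubic B-spline (P-spline) with equally
  spaced knots extending three segments beyond the data and a
  second-difference penalty on the coefficients; the equal spacing makes
  the penalty null space exactly the linear functions, so λ → ∞ recovers
  the OLS line and λ = 0 with a full basis interpolates. λ is chosen by
  generalized cross-validation on a log grid with bounded refinement.
  This smoother is a transparent stand-in for a GAM: it approximates, and
  does not replicate, any particular GAM implementation's basis or
  penalty.

## Field analysis

Cover is the mean ± sample SD across quadrats of 100 × kelp points / total
points; unreadable (zero-point) quadrats are excluded with a warning.
Growth is the increase in meristem-to-hole distance per day using the 5-cm
hole, falling back to the 10-cm hole for tattered blades; erosion is
(length_t0 + growth − length_t1)/days. Negative raw rates — measurement
noise — are floored at zero with a flag; the raw value is kept alongside.
Mortality is 100 × (lost tags + bladeless stipes)/total; lost tags count
as dead because dislodgement and tag loss are indistinguishable in the
field, and a lost-excluded sensitivity rate is reported alongside.
Monthly mortality defaults to linear division by the period length in
months; a compounding variant 100 × (1 − (1 − p)^(1/m)) is available
behind a flag. Neither convention is asserted as uniquely correct — the
choice matters at high mortality and the linear form matches the usual
field-report phrasing.

The turf-vs-kelp comparison fits mortality ~ reef state + (1 | region) by
maximum likelihood, profiling the variance ratio θ = σ²_region/σ²_resid on
a 1-D log grid with bounded refinement (the 2-region, ~10-site designs
involved make this more transparent and more robust than a general
mixed-model optimizer, and it is cross-checked against one in the tests).
The t statistic uses the containment-style df = n_sites − n_fixed −
n_regions, a small-sample convention; p comes from the t distribution with
that df. When the between-region variance collapses to zero the fit falls
back to OLS with region as a fixed effect, flagged as such.

## Synthetic world

`simulate_temperature` generates T(t) = mean + trend·years + seasonal
sinusoid + AR(1) noise. Defaults describe a warm-edge North Atlantic site:
mean 11 °C, seasonal amplitude 7 °C peaking in early August, warming trend
0.04 °C yr⁻¹, AR(1) φ = 0.8 with marginal SD 1 °C. `noise_sd` is the
*marginal* (stationary) SD, not the innovation SD, so statements like
"amplitude three times the noise SD" have their natural meaning. The red
noise is essential: white daily noise almost never produces the multi-day
exceedance runs real subsurface records show.

Injected anomalies (boxcar or half-sine) are added on top of the series
with an exact ground-truth ledger, and may not overlap, so detector
sensitivity and precision are scoreable without ambiguity.
`simulate_field_records` draws per-kelp deaths from
p = baseline + (max − baseline)·logistic(k·(maxT − threshold)) with
defaults threshold 19.7 °C, steepness 2 °C⁻¹ (a ~0.5 °C transition width,
consistent with acute thermal mortality), baseline 0.05 and ceiling 0.95;
survivors get log-normal growth (median 0.025 cm day⁻¹) and erosion
(median 0.2 cm day⁻¹) rates typical of late-summer sugar kelp.
`simulate_cover_history` is a one-line recursion — recovery toward a
carrying capacity minus losses proportional to annual exceedance — that
produces decline trajectories with changepoints, clipped to [0, 100].

What the generators deliberately do **not** emulate: spatially correlated
multi-site anomaly fields, sub-daily variability, non-stationary
seasonality, observational drift, or any ocean physics. Passing tests
demonstrate that the *computational chain* is correct under the stated
statistical structure, not that real records satisfy that structure.

### Noise-free exactness and benchmark design

Exact-recovery checks of injected boxcars use a hand-constructed flat
climatology (threshold a fixed gap above the mean) rather than a
climatology built from a pure sinusoid: circular smoothing attenuates a
sinusoid slightly, so "raw minus smoothed" is nonzero near the seasonal
peak and exact recovery would be ill-posed. The sensitivity benchmark
builds the climatology from an independent 30-year baseline realization of
the same process and injects 10-day boxcars of amplitude 3× the marginal
noise SD into 2-year test realizations; an injected event counts as
detected when any detected event overlaps it.

## Problem sizes

The verification suite uses 200 random series (200–500 days each) for
detector/oracle equivalence, 100 replicates for each of the sensitivity
and parameter-recovery benchmarks (100-year daily records for the warming
trend; 12 sites × 50 kelps for the mortality threshold), and exhaustive
grids elsewhere. These sizes give Monte-Carlo error well below the margins
being asserted while keeping the whole suite under a minute.

## Known limitations

* The published event-level numbers for specific station records (e.g.
  counts and durations of particular 2018 events) depend on the full
  external records and on unstated climatology parameters; the package
  reproduces the published *arithmetic* and verifies the *machinery*
  against oracles and synthetic ground truth instead.
* Quantile-trend inference (standard errors) is intentionally absent.
* The P-spline smoother approximates a GAM; effective df and fitted
  values will differ in detail from any specific GAM package.
* The frequency-trend endpoint arithmetic uses a 60-year span
  (start level + slope × 60) as its reading of a rise "over the 60-year
  record".
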