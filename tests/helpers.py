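"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written as plain loops over the definitions, sharing no code
with the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def brute_doy_curves(dates, values, window_half_width, smoothing_width):
    """Pooled day-of-year mean and 90th percentile by explicit loops, with
    circular smoothing and Feb 29 interpolation, on the 366-slot axis."""
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, float)
    # 365-axis labels, Feb 29 dropped
    labels = []
    for d in dates:
        if d.month == 2 and d.day == 29:
            labels.append(None)
        else:
            doy = d.dayofyear
            if d.is_leap_year and doy > 60:
                doy -= 1
            labels.append(doy - 1)
    mean365, p90_365 = np.empty(365), np.empty(365)
    for d in range(365):
        pooled = []
        for lab, v in zip(labels, values):
            if lab is None or not np.isfinite(v):
                continue
            diff = (lab - d) % 365
            if diff <= window_half_width or diff >= 365 - window_half_width:
                pooled.append(v)
        pooled = np.sort(np.asarray(pooled))
        mean365[d] = pooled.mean()
        # linear-interpolation percentile, by hand
        h = 0.90 * (len(pooled) - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, len(pooled) - 1)
        p90_365[d] = pooled[lo] + (h - lo) * (pooled[hi] - pooled[lo])
    if smoothing_width > 1:
        half = smoothing_width // 2
        sm_mean, sm_p90 = np.empty(365), np.empty(365)
        for d in range(365):
            idx = [(d + k) % 365 for k in range(-half, half + 1)]
            sm_mean[d] = np.mean(mean365[idx])
            sm_p90[d] = np.mean(p90_365[idx])
        mean365, p90_365 = sm_mean, sm_p90
    p90_365 = np.maximum(p90_365, mean365)

    def expand(c365):
        out = np.empty(366)
        out[:59] = c365[:59]
        out[59] = 0.5 * (c365[58] + c365[59])
        out[60:] = c365[59:]
        return out

    return expand(mean365), expand(p90_365)


def brute_event_segments(t, thr, min_duration=5, max_gap=2):
    """Run-length scan with gap joining, one day at a time.

    Returns inclusive (start, end) index pairs.  NaN breaks runs and
    forbids joining across the gap.
    """
    t = np.asarray(t, float)
    thr = np.asarray(thr, float)
    n = len(t)
    exceed = [bool(np.isfinite(t[i]) and t[i] > thr[i]) for i in range(n)]
    runs = []
    i = 0
    while i < n:
        if exceed[i]:
            j = i
            while j + 1 < n and exceed[j + 1]:
                j += 1
            if j - i + 1 >= min_duration:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    joined = []
    for run in runs:
        if joined:
            gap = list(range(joined[-1][1] + 1, run[0]))
            if len(gap) <= max_gap and all(np.isfinite(t[g]) for g in gap):
                joined[-1][1] = run[1]
                continue
        joined.append(run)
    return [(a, b) for a, b in joined]


def normal_equations_fit(x, y):
    """OLS by the textbook normal equations with the classical slope test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sse = np.sum(resid**2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    se = np.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, se, r2, p


def pinball(y, x, a, b, tau):
    r = np.asarray(y, float) - (a + b * np.asarray(x, float))
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def pair_enumeration_quantile(x, y, tau):
    """Exhaustive search over all lines through two data points (an optimal
    quantile-regression line passes through at least two points); ties
    broken by minimal |slope|."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = None
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[i] == x[j]:
                continue
            b = (y[j] - y[i]) / (x[j] - x[i])
            a = y[i] - b * x[i]
            loss = pinball(y, x, a, b, tau)
            if best is None or loss < best[0] - 1e-12 or (
                abs(loss - best[0]) <= 1e-12 and abs(b) < abs(best[2])
            ):
                best = (loss, a, b)
    return best  # (loss, intercept, slope)


def pearson_formula(x, y):
    """Pearson r and its t-test p-value straight from the formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p
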