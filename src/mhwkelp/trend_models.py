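"""Trend models for year-indexed heatwave metrics.

Three fits are provided:

* :func:`linear_trend` — ordinary least squares with the classical t-test
  on the slope (optionally AR(1)-adjusted standard errors);
* :func:`quantile_trend` — exact quantile regression (default tau = 0.90)
  via the linear-programming formulation of the check-loss problem, used
  to track change in the upper tail of event durations;
* :func:`spline_smooth` — a cubic P-spline smoother (second-difference
  penalty, lambda by generalized cross-validation) for nonlinear trends
  such as annual cumulative intensity.

The quantile fit is solved exactly (HiGHS simplex), with ties among
optimal lines broken by minimal absolute slope through a secondary LP.
The P-spline is a transparent penalized-regression stand-in for a GAM
smoother: it approximates, rather than replicates, any particular GAM
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import linprog, minimize_scalar

__all__ = ["TrendFit", "SmoothFit", "linear_trend", "quantile_trend", "spline_smooth"]


@dataclass(frozen=True)
class TrendFit:
    """A fitted straight-line trend.

    For OLS fits all fields are populated and ``tau`` is None.  For
    quantile fits ``slope_se``, ``r_squared`` and ``p_value`` are None:
    the LP point estimate is exact but no distributional standard error
    is attached.
    """

    slope: float
    intercept: float
    slope_se: float | None
    r_squared: float | None
    p_value: float | None
    n: int
    tau: float | None = None

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass
class SmoothFit:
    """A penalized cubic B-spline fit on the input years."""

    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    fitted: np.ndarray
    edf: float

    def predict(self, x) -> np.ndarray:
        return BSpline(self.knots, self.coefficients, 3)(np.asarray(x, float))


def _clean_pairs(years, values):
    x = np.asarray(years, float)
    y = np.asarray(values, float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def linear_trend(years, values, ar1_correction: bool = False) -> TrendFit:
    """OLS trend of a metric on year.

    R² = 1 - SSE/SST and the two-sided slope p-value comes from the t
    distribution with n - 2 df.  With ``ar1_correction`` the slope SE is
    inflated by the Bartlett factor sqrt((1 + rho)/(1 - rho)) using the
    lag-1 autocorrelation of the residuals (off by default, matching the
    plain linear-model convention).
    """
    x, y = _clean_pairs(years, values)
    n = len(x)
    if n < 3:
        raise ValueError("linear_trend requires at least 3 non-missing pairs")
    if np.ptp(x) == 0:
        raise ValueError("years have zero variance")
    res = stats.linregress(x, y)
    slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
    resid = y - (intercept + slope * x)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    if ar1_correction and n > 3:
        r = resid - resid.mean()
        denom = float((r**2).sum())
        rho = float((r[1:] * r[:-1]).sum()) / denom if denom > 0 else 0.0
        rho = min(max(rho, -0.99), 0.99)
        se *= np.sqrt((1 + rho) / (1 - rho))
    t = slope / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), n - 2)) if np.isfinite(t) else 0.0
    p = max(p, np.finfo(float).tiny)
    return TrendFit(slope, intercept, se, r2, p, n, tau=None)


def pinball_loss(y, x, intercept: float, slope: float, tau: float) -> float:
    """Check (pinball) loss of a candidate line, the quantity
    quantile_trend minimizes exactly."""
    r = np.asarray(y, float) - (intercept + slope * np.asarray(x, float))
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def quantile_trend(years, values, tau: float = 0.90) -> TrendFit:
    """Exact quantile regression of a metric on year.

    Minimizes the check loss sum rho_tau(y - a - b x) via its LP
    formulation; among loss-optimal lines the one with minimal |b| is
    returned (secondary LP).  Requires at least 10 points for tau in the
    tails (|tau - 0.5| > 0.25), 5 otherwise.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    x, y = _clean_pairs(years, values)
    n = len(x)
    min_n = 10 if abs(tau - 0.5) > 0.25 else 5
    if n < min_n:
        raise ValueError(f"quantile_trend at tau={tau} requires >= {min_n} pairs")
    if np.ptp(x) == 0:
        raise ValueError("years have zero variance")

    # scale x for LP conditioning; un-scale the slope afterwards
    x0, xs = x.mean(), np.ptp(x)
    xc = (x - x0) / xs

    # variables: a+, a-, b+, b-, u_1..u_n, v_1..v_n  (all >= 0)
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = xc
    A_eq[:, 3] = -xc
    A_eq[:, 4 : 4 + n] = np.eye(n)
    A_eq[:, 4 + n :] = -np.eye(n)
    res = linprog(c, A_eq=A_eq, b_eq=y, method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"quantile LP failed: {res.message}")
    best = float(res.fun)

    # tie-break: minimal |b| among (near-)optimal lines
    c2 = np.zeros(4 + 2 * n)
    c2[2] = c2[3] = 1.0
    eps = 1e-9 * (1.0 + abs(best))
    res2 = linprog(
        c2, A_ub=c[None, :], b_ub=[best + eps], A_eq=A_eq, b_eq=y, method="highs"
    )
    z = res2.x if res2.success else res.x
    a = float(z[0] - z[1])
    b = float(z[2] - z[3])

    # an optimal quantile line passes through >= 2 data points: snap onto the
    # nearest vertex to remove LP tolerance slack, keeping minimal |b| on ties
    def loss(ai: float, bi: float) -> float:
        r = y - (ai + bi * xc)
        return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))

    candidates = [(a, b)]
    support = np.argsort(np.abs(y - (a + b * xc)))[: min(n, 4)]
    for ii in range(len(support)):
        for jj in range(ii + 1, len(support)):
            i, j = support[ii], support[jj]
            if xc[i] == xc[j]:
                continue
            bb = (y[j] - y[i]) / (xc[j] - xc[i])
            candidates.append((y[i] - bb * xc[i], bb))
    losses = [loss(ai, bi) for ai, bi in candidates]
    lo = min(losses)
    tol = 1e-12 * (1.0 + abs(lo))
    a, b = min(
        (cand for cand, l in zip(candidates, losses) if l <= lo + tol),
        key=lambda cand: abs(cand[1]),
    )
    slope = b / xs
    intercept = a - slope * x0
    return TrendFit(slope, intercept, None, None, None, n, tau=tau)


def _pspline_design(x: np.ndarray, nbasis: int) -> tuple[np.ndarray, np.ndarray]:
    # equally spaced knots extending k segments beyond the data, the classic
    # P-spline construction: Greville sites are then equally spaced, so the
    # second-difference penalty's null space is exactly the linear functions
    k = 3
    nseg = nbasis - k
    h = (x[-1] - x[0]) / nseg
    t = x[0] + h * np.arange(-k, nseg + k + 1)
    B = BSpline.design_matrix(x, t, k, extrapolate=True).toarray()
    return t, B


def spline_smooth(years, values, lam: float | None = None, nbasis: int | None = None) -> SmoothFit:
    """Cubic P-spline smoother of a metric on year.

    B-spline basis (degree 3, interior knots at quantiles of the years)
    with a second-difference penalty on the coefficients; the penalty
    weight is chosen by generalized cross-validation over a log grid with
    bounded refinement unless ``lam`` is given.  As lam -> infinity the
    fit tends to the OLS line (the penalty null space); with lam = 0 and
    nbasis = n it interpolates the data.
    """
    x, y = _clean_pairs(years, values)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 8:
        raise ValueError("spline_smooth requires >= 8 points; use linear_trend instead")
    if nbasis is None:
        nbasis = min(n, max(8, n // 2 + 2))
    nbasis = int(min(nbasis, n))
    t, B = _pspline_design(x, nbasis)
    D = np.diff(np.eye(nbasis), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y

    def fit_at(l: float):
        coef = np.linalg.solve(BtB + l * P + 1e-12 * np.eye(nbasis), Bty)
        fitted = B @ coef
        H_diag_trace = np.trace(
            np.linalg.solve(BtB + l * P + 1e-12 * np.eye(nbasis), BtB)
        )
        return coef, fitted, float(H_diag_trace)

    def gcv(log10_l: float) -> float:
        l = 10.0**log10_l
        _, fitted, edf = fit_at(l)
        rss = float(((y - fitted) ** 2).sum())
        denom = max(n - edf, 1e-8)
        return n * rss / denom**2

    if lam is None:
        grid = np.linspace(-6, 8, 57)
        scores = [gcv(g) for g in grid]
        g0 = grid[int(np.argmin(scores))]
        res = minimize_scalar(gcv, bounds=(g0 - 1.0, g0 + 1.0), method="bounded")
        lam = float(10.0**res.x)
    lam = float(lam)
    coef, fitted, edf = fit_at(lam)
    return SmoothFit(knots=t, coefficients=coef, lam=lam, fitted=fitted, edf=edf)
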