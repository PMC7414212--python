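"""Field-experiment computations for tagged and transplanted kelps.

Implements the arithmetic behind an in situ kelp mortality study: percent
cover from photo-quadrat point counts, blade growth from hole-punch
displacement, distal erosion, mortality rates of tagged/transplanted
individuals, monthly-rate conversion, Pearson correlation tests, a
random-intercept comparison of mortality on turf- versus kelp-dominated
reefs, and the light-logger fouling filter.

Conventions (each flagged where applied):

* growth uses the 5-cm hole, falling back to the 10-cm hole when the
  blade tip is tattered and the 5-cm mark was lost;
* negative raw growth/erosion (measurement noise) is floored at 0;
* "lost" tags count as dead, with an optional sensitivity rate that
  excludes them;
* monthly mortality is total mortality divided by the period length in
  months (a compounding variant is available behind a flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "TagRecord",
    "SiteSummary",
    "QuadratCount",
    "CoverSummary",
    "RateResult",
    "MortalitySummary",
    "PearsonResult",
    "MixedModelFit",
    "cover_from_points",
    "growth_rate",
    "erosion_rate",
    "mortality_rate",
    "to_monthly_rate",
    "pearson_test",
    "turf_vs_kelp_model",
    "light_filter",
    "fit_mortality_threshold",
]

FATES = ("alive", "dead_bladeless", "lost")
ROLES = ("tagged", "transplant", "control")


@dataclass
class TagRecord:
    """One tagged or transplanted kelp followed across two visits.

    Lengths and hole distances are in cm; hole distances are measured
    from the meristem.  ``_t1`` fields are None when the individual was
    lost or the mark could not be relocated.
    """

    site_id: str
    kelp_id: str
    role: str
    fate: str
    period_days: int
    length_t0: float
    length_t1: float | None = None
    hole5_t0: float | None = None
    hole10_t0: float | None = None
    hole5_t1: float | None = None
    hole10_t1: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.fate not in FATES:
            raise ValueError(f"fate must be one of {FATES}")
        for name in ("length_t0", "length_t1", "hole5_t0", "hole10_t0", "hole5_t1", "hole10_t1"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fate == "alive" and self.length_t1 is None:
            raise ValueError("an alive kelp must have a second blade-length measure")
        if self.period_days <= 0:
            raise ValueError("period_days must be positive")


@dataclass
class SiteSummary:
    site_id: str
    state: str  # kelp_dominated | turf_dominated
    region: str  # e.g. S_Norway | E_USA
    max_temp: float
    mean_temp: float
    mortality_pct: float
    growth_cm_day: float | None = None
    erosion_cm_day: float | None = None
    light_klux: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mortality_pct <= 100:
            raise ValueError("mortality_pct must lie in [0, 100]")
        if self.state not in ("kelp_dominated", "turf_dominated"):
            raise ValueError("state must be kelp_dominated or turf_dominated")


@dataclass
class QuadratCount:
    quadrat_id: str
    points_total: int
    points_kelp: int

    def __post_init__(self) -> None:
        if not 0 <= self.points_kelp <= self.points_total:
            raise ValueError("need 0 <= points_kelp <= points_total")


@dataclass(frozen=True)
class CoverSummary:
    mean_pct: float
    sd_pct: float
    n_quadrats: int


@dataclass(frozen=True)
class RateResult:
    """A per-day rate with provenance flags."""

    value: float  # cm day^-1, floored at 0
    raw_value: float  # before flooring
    floored: bool
    source: str  # which measurement the rate came from


@dataclass(frozen=True)
class MortalitySummary:
    mortality_pct: float
    n_total: int
    n_lost: int
    n_dead_bladeless: int
    n_alive: int
    lost_excluded_pct: float  # sensitivity rate counting only bladeless stipes

    @property
    def survival_pct(self) -> float:
        return 100.0 - self.mortality_pct


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class MixedModelFit:
    estimate: float
    se: float
    t_stat: float
    df: int
    p_value: float
    region_sd: float
    resid_sd: float
    used_ols_fallback: bool


def cover_from_points(quadrats: Sequence[QuadratCount]) -> CoverSummary:
    """Site percent cover from point counts: per-quadrat cover is
    100 × kelp points / total points; the site value is the mean ± sample
    SD across quadrats.  Zero-point quadrats (unreadable images) are
    excluded with a warning."""
    usable = []
    for q in quadrats:
        if q.points_total == 0:
            warnings.warn(f"quadrat {q.quadrat_id} has no points; excluded", stacklevel=2)
            continue
        usable.append(100.0 * q.points_kelp / q.points_total)
    if not usable:
        raise ValueError("no usable quadrats (all had zero points)")
    arr = np.asarray(usable)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CoverSummary(mean_pct=float(arr.mean()), sd_pct=sd, n_quadrats=len(arr))


def _hole_growth_cm(rec: TagRecord) -> tuple[float, str]:
    if rec.hole5_t1 is not None and rec.hole5_t0 is not None:
        return rec.hole5_t1 - rec.hole5_t0, "hole5"
    if rec.hole10_t1 is not None and rec.hole10_t0 is not None:
        return rec.hole10_t1 - rec.hole10_t0, "hole10"
    raise ValueError(
        f"kelp {rec.kelp_id}: no hole mark relocated at the second visit; "
        "growth undefined"
    )


def growth_rate(rec: TagRecord) -> RateResult:
    """Blade growth as the increase in meristem-to-hole distance divided by
    the period, using the 5-cm hole (10-cm hole for tattered blades).
    Negative raw values are floored at 0 and flagged."""
    if rec.fate != "alive":
        raise ValueError("growth is defined only for kelps alive at the second visit")
    growth_cm, source = _hole_growth_cm(rec)
    raw = growth_cm / rec.period_days
    return RateResult(value=max(raw, 0.0), raw_value=raw, floored=raw < 0, source=source)


def erosion_rate(rec: TagRecord) -> RateResult:
    """Distal erosion: the blade-length decrease between visits after
    crediting basal growth, per day.  Floored at 0 and flagged when the
    blade lengthened more than it grew."""
    if rec.fate != "alive":
        raise ValueError("erosion is defined only for kelps alive at the second visit")
    if rec.length_t1 is None:
        raise ValueError("erosion requires blade length at both visits")
    growth_cm, source = _hole_growth_cm(rec)
    total_growth = max(growth_cm, 0.0)
    raw = (rec.length_t0 + total_growth - rec.length_t1) / rec.period_days
    return RateResult(value=max(raw, 0.0), raw_value=raw, floored=raw < 0, source=source)


def mortality_rate(recs: Sequence[TagRecord]) -> MortalitySummary:
    """Mortality as 100 × (lost tags + bladeless stipes) / tagged total.

    Lost tags count as dead (dislodgement is indistinguishable from tag
    loss); ``lost_excluded_pct`` reports the sensitivity rate counting
    only bladeless stipes."""
    if not recs:
        raise ValueError("mortality_rate requires at least one record")
    n = len(recs)
    n_lost = sum(1 for r in recs if r.fate == "lost")
    n_blade = sum(1 for r in recs if r.fate == "dead_bladeless")
    n_alive = n - n_lost - n_blade
    return MortalitySummary(
        mortality_pct=100.0 * (n_lost + n_blade) / n,
        n_total=n,
        n_lost=n_lost,
        n_dead_bladeless=n_blade,
        n_alive=n_alive,
        lost_excluded_pct=100.0 * n_blade / n,
    )


def to_monthly_rate(total_pct: float, period_months: float, compounding: bool = False) -> float:
    """Convert a whole-period mortality percentage to % per month.

    Default is linear division by the period length.  The compounding
    variant 100 × (1 - (1 - p)^(1/m)) treats mortality as a constant
    monthly hazard instead."""
    if period_months <= 0:
        raise ValueError("period_months must be positive")
    if compounding:
        p = total_pct / 100.0
        if not 0 <= p <= 1:
            raise ValueError("compounding conversion requires 0 <= total_pct <= 100")
        return 100.0 * (1.0 - (1.0 - p) ** (1.0 / period_months))
    return total_pct / period_months


def pearson_test(x, y) -> PearsonResult:
    """Pearson product-moment correlation with the two-sided t-test
    p-value, t = r sqrt((n-2)/(1-r²))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("pearson_test requires at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_test requires non-constant variables")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=n)


def _design(sites: Sequence[SiteSummary]):
    y = np.array([s.mortality_pct for s in sites], float)
    state = np.array([1.0 if s.state == "turf_dominated" else 0.0 for s in sites])
    regions = sorted({s.region for s in sites})
    Z = np.column_stack([(np.array([s.region for s in sites]) == r).astype(float) for r in regions])
    X = np.column_stack([np.ones(len(sites)), state])
    return y, X, Z, regions


def turf_vs_kelp_model(sites: Sequence[SiteSummary], min_theta: float = 1e-6) -> MixedModelFit:
    """Random-intercept comparison of mortality on turf- vs kelp-dominated
    reefs: mortality ~ reef state + (1 | region), fitted by maximum
    likelihood with the variance ratio profiled on a 1-D grid plus bounded
    refinement.

    Returns the reef-state fixed effect with its t statistic on
    df = n_sites - n_fixed - n_regions and the two-sided p from the t
    distribution.  When the between-region variance collapses to zero the
    fit falls back to OLS with region as a fixed effect, flagged."""
    y, X, Z, regions = _design(sites)
    n, p = X.shape
    r = Z.shape[1]
    if r < 2:
        raise ValueError("need at least two regions")
    for j in range(r):
        if Z[:, j].sum() < 2:
            raise ValueError(f"region {regions[j]} has fewer than 2 sites")
    if len(set(X[:, 1])) < 2:
        raise ValueError("both reef states must be represented")
    df = n - p - r
    if df < 1:
        raise ValueError("too few sites for the df convention n - n_fixed - n_regions")

    ZZt = Z @ Z.T
    eye = np.eye(n)

    def profile(theta: float):
        V = eye + theta * ZZt
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        beta = np.linalg.solve(XtVi @ X, XtVi @ y)
        resid = y - X @ beta
        sig2 = float(resid @ Vi @ resid) / n
        sign, logdet = np.linalg.slogdet(V)
        ll = -0.5 * (n * math.log(2 * math.pi * max(sig2, 1e-300)) + logdet + n)
        return ll, beta, sig2, Vi

    def negll(log10_theta: float) -> float:
        return -profile(10.0**log10_theta)[0]

    grid = np.linspace(-10, 6, 65)
    scores = [negll(g) for g in grid]
    g0 = grid[int(np.argmin(scores))]
    res = minimize_scalar(negll, bounds=(g0 - 0.5, g0 + 0.5), method="bounded")
    theta = float(10.0**res.x)

    if theta < min_theta or negll(math.log10(min_theta)) <= res.fun + 1e-9:
        # singular fit: between-region variance ~ 0 -> OLS with region fixed
        Xf = np.column_stack([X, Z[:, 1:]])
        beta, _, _, _ = np.linalg.lstsq(Xf, y, rcond=None)
        resid = y - Xf @ beta
        sig2 = float(resid @ resid) / max(n - Xf.shape[1], 1)
        cov = sig2 * np.linalg.inv(Xf.T @ Xf)
        est, se = float(beta[1]), float(math.sqrt(cov[1, 1]))
        t = est / se if se > 0 else 0.0
        return MixedModelFit(
            estimate=est,
            se=se,
            t_stat=t,
            df=df,
            p_value=float(2 * stats.t.sf(abs(t), df)),
            region_sd=0.0,
            resid_sd=float(math.sqrt(sig2)),
            used_ols_fallback=True,
        )

    _, beta, sig2, Vi = profile(theta)
    cov = sig2 * np.linalg.inv(X.T @ Vi @ X)
    est, se = float(beta[1]), float(math.sqrt(cov[1, 1]))
    t = est / se if se > 0 else 0.0
    return MixedModelFit(
        estimate=est,
        se=se,
        t_stat=t,
        df=df,
        p_value=float(2 * stats.t.sf(abs(t), df)),
        region_sd=float(math.sqrt(theta * sig2)),
        resid_sd=float(math.sqrt(sig2)),
        used_ols_fallback=False,
    )


def light_filter(light_series: pd.Series, deploy_date) -> pd.Series:
    """Keep only the first two weeks of a light-logger record so biofouling
    does not bias the light measurements: samples after
    deploy_date + 14 days are dropped."""
    if len(light_series) == 0:
        return light_series.copy()
    cutoff = pd.Timestamp(deploy_date) + pd.Timedelta(days=14)
    return light_series[light_series.index < cutoff].copy()


def fit_mortality_threshold(
    max_temps,
    n_dead,
    n_total,
    steepness: float,
    baseline_p: float,
    max_p: float,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Maximum-likelihood estimate of the temperature threshold in the
    saturating-logistic mortality model

        p(T) = baseline_p + (max_p - baseline_p) * logistic(steepness * (T - thr)),

    from per-site binomial death counts, with the other parameters held
    fixed.  Used to check that threshold location is recoverable from
    site-level mortality data."""
    T = np.asarray(max_temps, float)
    dead = np.asarray(n_dead, float)
    tot = np.asarray(n_total, float)
    if bounds is None:
        bounds = (float(T.min() - 5.0), float(T.max() + 5.0))

    def negll(thr: float) -> float:
        p = baseline_p + (max_p - baseline_p) * expit(steepness * (T - thr))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(dead * np.log(p) + (tot - dead) * np.log1p(-p)))

    res = minimize_scalar(negll, bounds=bounds, method="bounded")
    return float(res.x)
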