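"""Estimation, smoothing and trend projection of transition probabilities.

Annual transition probabilities are estimated as occurrence/exposure ratios
(events divided by start-of-year persons at risk) within each
age x gender x quintile x calendar-year cell, stabilised over age with a
shape-preserving smoother, and projected to the simulation horizon:

* mortality: a smooth-additive (GAM-style) calendar trend per
  gender x quintile x 10-year age band on the log scale, fit to 1995-2018
  and extrapolated log-linearly from the fitted end slope; the T2D vs
  non-T2D mortality ratio is frozen at its fitted 2019 value within each
  stratum, keeping the differentials constant at 2019 levels;
* incidence, baseline scenario: held constant at the 2019 level;
* incidence, scenario A: log-linear continuation of the post-2011 decline,
  with the 2007-2010 diagnosis-surge years excluded from fitting wherever
  the fit window touches them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit, logit

from .probset import AGE_MAX, AGE_MIN, GENDERS, QUINTILES, TransitionProbabilitySet

EPS = 1e-8
_LOGIT_CAP = 36.0
# calendar-trend slopes are estimated from ages up to this limit: the terminal
# age (certain death) and near-saturated old-age cells carry no trend signal
# and would flatten a pooled log-scale series
TREND_AGE_MAX = 89


# ----------------------------------------------------------------------
# occurrence/exposure estimation
# ----------------------------------------------------------------------
def estimate_transition_probabilities(counts: pd.DataFrame) -> TransitionProbabilitySet:
    """Raw cell-wise estimates p = events / persons at risk.

    ``counts`` is the tidy occurrence/exposure table from
    :func:`t2dms.synth_register.aggregate_counts`.  Cells with zero at-risk
    persons are left missing (NaN) for the age smoother to fill; cells with
    exposure but no events are genuine zeros.  Exposure counts are attached
    to the returned set for downstream weighting.
    """
    for ev, ar in (("n_incident", "n_free"), ("n_death_free", "n_free"), ("n_death_t2d", "n_t2d")):
        if (counts[ev] > counts[ar]).any():
            raise ValueError(f"{ev} exceeds at-risk column {ar}")
    years = np.sort(counts["year"].unique())
    out = TransitionProbabilitySet.empty(years)
    shape = out.p_inc.shape
    n_free = np.zeros(shape)
    n_t2d = np.zeros(shape)
    inc = np.zeros(shape)
    d_free = np.zeros(shape)
    d_t2d = np.zeros(shape)

    ai = np.clip(counts["age"].to_numpy(int), AGE_MIN, AGE_MAX) - AGE_MIN
    gi = pd.Categorical(counts["gender"], categories=list(GENDERS)).codes
    qi = counts["quintile"].to_numpy(int) - 1
    ti = np.searchsorted(years, counts["year"].to_numpy())
    for arr, col in (
        (n_free, "n_free"),
        (n_t2d, "n_t2d"),
        (inc, "n_incident"),
        (d_free, "n_death_free"),
        (d_t2d, "n_death_t2d"),
    ):
        np.add.at(arr, (ai, gi, qi, ti), counts[col].to_numpy(float))

    with np.errstate(invalid="ignore", divide="ignore"):
        out.p_inc = np.where(n_free > 0, inc / n_free, np.nan)
        out.p_m_free = np.where(n_free > 0, d_free / n_free, np.nan)
        out.p_m_t2d = np.where(n_t2d > 0, d_t2d / n_t2d, np.nan)
    out.exposure_free = n_free
    out.exposure_t2d = n_t2d
    out.validate()
    return out


# ----------------------------------------------------------------------
# age smoothing
# ----------------------------------------------------------------------
def _smooth_profile(ages, p, weights, min_at_risk):
    """Fill/stabilise one age profile on the logit scale.

    Cells backed by at least ``min_at_risk`` persons act as anchors and are
    returned unchanged; all other cells are interpolated through the
    anchors with a monotonicity-preserving PCHIP on the logit scale (linear
    continuation beyond the anchor range).
    """
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("age profile is entirely missing")
    anchors = finite & (weights >= min_at_risk)
    if anchors.sum() < 2:
        anchors = finite
    if anchors.sum() < 2:
        return np.where(finite, p, p[finite][0])
    xa = ages[anchors].astype(float)
    ya = logit(np.clip(p[anchors], EPS, 1 - EPS))
    interp = PchipInterpolator(xa, ya, extrapolate=False)
    z = interp(ages.astype(float))
    # linear extrapolation from the endpoint slopes
    d = interp.derivative()
    lo, hi = xa[0], xa[-1]
    below = ages < lo
    above = ages > hi
    z[below] = ya[0] + float(d(lo)) * (ages[below] - lo)
    z[above] = ya[-1] + float(d(hi)) * (ages[above] - hi)
    smoothed = expit(np.clip(z, -_LOGIT_CAP, _LOGIT_CAP))
    return np.where(anchors, p, smoothed)


def smooth_over_age(
    probs: TransitionProbabilitySet,
    min_at_risk: float = 500.0,
    on_missing: str = "raise",
) -> TransitionProbabilitySet:
    """Smooth each probability surface over age within gender x quintile x year.

    Well-observed cells (at-risk count >= ``min_at_risk``) pass through
    unchanged; sparse and missing cells are interpolated between them on
    the logit scale.  Exposure arrays provide the anchor weights when
    available; without them, every observed cell anchors the interpolant.
    An entirely missing age profile raises by default; ``on_missing='skip'``
    leaves it NaN (for sparse strata, to be filled by
    :func:`fill_missing`).
    """
    if on_missing not in ("raise", "skip"):
        raise ValueError("on_missing must be 'raise' or 'skip'")
    out = probs.copy()
    specs = (
        ("p_inc", probs.exposure_free),
        ("p_m_free", probs.exposure_free),
        ("p_m_t2d", probs.exposure_t2d),
    )
    ages = probs.ages
    for name, expo in specs:
        src = getattr(probs, name)
        dst = getattr(out, name)
        for g in range(len(GENDERS)):
            for q in range(len(QUINTILES)):
                for t in range(len(probs.years)):
                    w = expo[:, g, q, t] if expo is not None else np.full(len(ages), np.inf)
                    try:
                        dst[:, g, q, t] = _smooth_profile(ages, src[:, g, q, t], w, min_at_risk)
                    except ValueError:
                        if on_missing == "raise":
                            raise
    out = enforce_joint_constraint(out)
    out.validate()
    return out


def fill_missing(probs: TransitionProbabilitySet) -> TransitionProbabilitySet:
    """Borrow values for cells still missing after smoothing.

    Fills NaN cells from the mean over quintiles, then over genders, then
    over years (all NaN-aware); anything still missing becomes 0 for
    incidence and the overall age-profile mean for mortality.
    """
    out = probs.copy()
    for name in ("p_inc", "p_m_free", "p_m_t2d"):
        arr = getattr(out, name)
        if np.isfinite(arr).all():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for axis in (2, 1, 3):  # quintile, gender, year
                fill = np.nanmean(arr, axis=axis, keepdims=True)
                arr = np.where(np.isnan(arr), np.broadcast_to(fill, arr.shape), arr)
            age_mean = np.nanmean(arr, axis=(1, 2, 3), keepdims=True)
        default = 0.0 if name == "p_inc" else np.nan_to_num(age_mean, nan=EPS)
        arr = np.where(np.isnan(arr), np.broadcast_to(default, arr.shape) if name != "p_inc" else 0.0, arr)
        setattr(out, name, arr)
    out = enforce_joint_constraint(out)
    out.validate()
    return out


# ----------------------------------------------------------------------
# calendar-trend machinery
# ----------------------------------------------------------------------
def _age_bands(width: int | None):
    """Age bands for trend pooling; ``None`` pools the full 30-100 range."""
    if width is None:
        return [(AGE_MIN, AGE_MAX)]
    bands = []
    for lo in range(AGE_MIN, 100, width):
        hi = lo + width - 1
        if hi + width > AGE_MAX:
            hi = AGE_MAX
        bands.append((lo, hi))
        if hi == AGE_MAX:
            break
    return bands


def extend_years(probs: TransitionProbabilitySet, horizon: int) -> TransitionProbabilitySet:
    """Widen the year axis to ``horizon``; new cells are missing (NaN)."""
    if horizon <= probs.years[-1]:
        return probs.copy()
    years = np.arange(probs.years[0], horizon + 1)
    out = TransitionProbabilitySet.empty(years)
    sel = np.searchsorted(years, probs.years)
    for name in ("p_inc", "p_m_free", "p_m_t2d"):
        getattr(out, name)[..., sel] = getattr(probs, name)
    out.exposure_free = None if probs.exposure_free is None else _pad_years(probs.exposure_free, len(years), sel)
    out.exposure_t2d = None if probs.exposure_t2d is None else _pad_years(probs.exposure_t2d, len(years), sel)
    return out


def _pad_years(arr, n_years, sel):
    out = np.zeros(arr.shape[:-1] + (n_years,))
    out[..., sel] = arr
    return out


def _band_series(p_slab, w_slab, years_mask):
    """Weighted mean probability per year over one age band.

    Weights are the time-averaged exposures per age (fixed across years),
    so shifting age composition cannot masquerade as a calendar trend.
    """
    p = p_slab[:, years_mask]
    w = w_slab[:, years_mask]
    w = np.where(np.isfinite(p), w, 0.0)
    w_fixed = w.mean(axis=1, keepdims=True) * np.isfinite(p)
    num = np.nansum(p * w_fixed, axis=0)
    den = w_fixed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _aligned_base(slab, w_slab, years, slope, ref_year, window):
    """Per-age base level at ``ref_year``: trend-aligned mean of recent years.

    Each of the last ``window`` observed years is shifted to ``ref_year``
    along the fitted log-trend before exposure-weighted averaging, which
    shrinks single-year noise without biasing the level.
    """
    recent = (years <= ref_year) & (years > ref_year - window)
    p = slab[:, recent]
    w = np.where(np.isfinite(p), w_slab[:, recent], 0.0)
    align = np.exp(slope * (ref_year - years[recent]))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(p * align * w, axis=1)
        den = w.sum(axis=1)
        base = np.where(den > 0, num / den, np.nan)
    # cells unobserved in the whole window fall back to the ref-year value
    ref_col = slab[:, years == ref_year]
    if ref_col.shape[1] == 1:
        base = np.where(np.isnan(base), ref_col[:, 0], base)
    return base


def _fit_log_gam(x, y, alpha=1.0, slope_window=None):
    """Penalised-spline fit of log level vs year; returns (fitted, slope).

    The extrapolation slope is the least-squares slope of the fitted
    smooth over the whole window (or the last ``slope_window`` years when
    given): penalised splines flatten at the boundary, so a short
    end-window slope is biased toward zero under noise.  Falls back to a
    log-linear fit when the smooth fit fails or is non-finite (logged).
    """
    from statsmodels.gam.api import GLMGam, BSplines
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    fitted = None
    warn = False
    if len(x) >= 8:
        try:
            bs = BSplines(x[:, None], df=[5], degree=[3], include_intercept=False)
            model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, alpha=[alpha])
            res = model.fit()
            fitted = np.asarray(res.fittedvalues)
            if not np.all(np.isfinite(fitted)):
                fitted = None
                warn = True
        except PerfectSeparationError:
            fitted = None  # residual-free series: the linear fallback is exact
        except Exception:
            fitted = None
            warn = True
    if fitted is None:
        if warn:
            warnings.warn("smooth trend fit failed; falling back to log-linear", stacklevel=2)
        b, a = np.polyfit(x, y, 1)
        fitted = a + b * x
        return fitted, float(b)
    near_end = x >= x[-1] - slope_window if slope_window else np.ones_like(x, dtype=bool)
    if near_end.sum() >= 2:
        slope = np.polyfit(x[near_end], fitted[near_end], 1)[0]
    else:
        slope = (fitted[-1] - fitted[0]) / (x[-1] - x[0])
    return fitted, float(slope)


# ----------------------------------------------------------------------
# mortality trend projection (baseline and all scenarios)
# ----------------------------------------------------------------------
def fit_mortality_trend(
    probs: TransitionProbabilitySet,
    fit_start: int = 1995,
    fit_end: int = 2018,
    horizon: int = 2040,
    band_width: int | None = None,
    alpha: float = 1.0,
    base_window: int = 5,
) -> TransitionProbabilitySet:
    """Project mortality to ``horizon`` from its 1995-2018 calendar trend.

    Per gender x quintile (x age band when ``band_width`` is set; by default
    the calendar trend is pooled over all ages, which the sparse strata of
    desk-scale registers require), the pooled log mortality of each state
    is fit with a penalised spline over the fit years and continued
    log-linearly from the fitted end slope.  Each age cell's projection
    scales its trend-aligned recent level (mean of the last ``base_window``
    observed years) by the trend multiplier.  T2D mortality is then pinned
    to the projected free-state mortality through the ratio of the two
    fitted 2019 values, so the T2D / non-T2D differential stays at its
    2019 level in every stratum.  Incidence is copied for historical years
    and left missing for future years (the scenario rules fill it).
    """
    fit_years_mask = (probs.years >= fit_start) & (probs.years <= fit_end)
    if fit_years_mask.sum() < 10:
        raise ValueError("need at least 10 fit years for the mortality trend")
    out = extend_years(probs, horizon)
    target = out.years[out.years > fit_end]
    ti_target = np.searchsorted(out.years, target)
    x = probs.years[fit_years_mask].astype(float)

    for g in range(len(GENDERS)):
        for q in range(len(QUINTILES)):
            for lo, hi in _age_bands(band_width):
                a_sel = slice(lo - AGE_MIN, hi - AGE_MIN + 1)
                a_fit = slice(lo - AGE_MIN, min(hi, TREND_AGE_MAX) - AGE_MIN + 1)
                for name, expo in (("p_m_free", probs.exposure_free), ("p_m_t2d", probs.exposure_t2d)):
                    slab = getattr(probs, name)[a_sel, g, q, :]
                    w_slab = (
                        expo[a_sel, g, q, :]
                        if expo is not None
                        else np.ones_like(slab)
                    )
                    fit_slab = getattr(probs, name)[a_fit, g, q, :]
                    fit_w = (
                        expo[a_fit, g, q, :] if expo is not None else np.ones_like(fit_slab)
                    )
                    series = _band_series(fit_slab, fit_w, fit_years_mask)
                    ok = np.isfinite(series) & (series > 0)
                    if ok.sum() < 4:
                        slope = 0.0
                        mult = np.ones_like(target, dtype=float)
                    else:
                        _, slope = _fit_log_gam(
                            x[ok], np.log(np.clip(series[ok], EPS, 1.0)), alpha=alpha
                        )
                        mult = np.exp(slope * (target - x[ok][-1]))
                    base = _aligned_base(
                        slab, w_slab, probs.years, slope, fit_end, base_window
                    )
                    proj = base[:, None] * mult[None, :]
                    getattr(out, name)[a_sel, g, q, ti_target] = np.clip(proj, EPS, 1 - EPS)

    # freeze the T2D:free mortality ratio at its fitted 2019 value
    ref_year = fit_end + 1
    tr = out.year_index(ref_year)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = out.p_m_t2d[..., tr] / out.p_m_free[..., tr]
    ratio = np.where(np.isfinite(ratio), ratio, 1.0)
    for t in ti_target:
        out.p_m_t2d[..., t] = np.clip(ratio * out.p_m_free[..., t], EPS, 1 - EPS)
    out = enforce_joint_constraint(out)
    out.enforce_terminal_age()
    out.validate()
    return out


# ----------------------------------------------------------------------
# incidence rules
# ----------------------------------------------------------------------
def _pooled_incidence_slopes(
    probs: TransitionProbabilitySet, fit_mask: np.ndarray, pool_quintiles: bool
) -> np.ndarray:
    """Log-linear incidence slope per gender (x quintile when not pooled).

    Quintile-pooled by default: a per-stratum 8-point series rarely carries
    enough incident events to identify a slope of the order of 1%/year.
    Returns an array of shape (2, 5).
    """
    x = probs.years[fit_mask].astype(float)
    slopes = np.zeros((len(GENDERS), len(QUINTILES)))
    a_hi = TREND_AGE_MAX - AGE_MIN + 1
    q_groups = [list(range(len(QUINTILES)))] if pool_quintiles else [[q] for q in range(5)]
    for g in range(len(GENDERS)):
        for qs in q_groups:
            slab = probs.p_inc[:a_hi, g, qs, :].reshape(-1, len(probs.years))
            if probs.exposure_free is not None:
                w_slab = probs.exposure_free[:a_hi, g, qs, :].reshape(-1, len(probs.years))
            else:
                w_slab = np.ones_like(slab)
            series = _band_series(slab, w_slab, fit_mask)
            ok = np.isfinite(series) & (series > 0)
            slope = np.polyfit(x[ok], np.log(series[ok]), 1)[0] if ok.sum() >= 2 else 0.0
            if slope > 1e-6:
                warnings.warn(
                    f"fitted incidence trend is rising ({GENDERS[g]}): {slope:+.4f}/yr",
                    stacklevel=3,
                )
            slopes[g, qs] = slope
    return slopes


def stabilize_incidence_level(
    probs: TransitionProbabilitySet,
    at_year: int = 2019,
    window: int = 5,
    trend_from: int = 2011,
    exclude: tuple[int, int] | None = (2007, 2010),
) -> TransitionProbabilitySet:
    """Replace the ``at_year`` incidence slice with a denoised estimate.

    The level is the exposure-weighted mean of the last ``window`` observed
    years, each aligned to ``at_year`` along a pooled log-linear recent
    trend per gender x quintile.  Single-year cell estimates at realistic
    register sizes are far too noisy to freeze a 20-year projection on;
    this keeps the baseline rule ("incidence constant at the 2019 level")
    while estimating that level from more than one year of data.
    """
    out = probs.copy()
    fit_mask = (probs.years >= trend_from) & (probs.years <= at_year)
    if exclude is not None:
        fit_mask &= ~((probs.years >= exclude[0]) & (probs.years <= exclude[1]))
    t_at = out.year_index(at_year)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rising-trend warnings surface in scenario A
        slopes = _pooled_incidence_slopes(probs, fit_mask, pool_quintiles=True)
    for g in range(len(GENDERS)):
        for q in range(len(QUINTILES)):
            slab = probs.p_inc[:, g, q, :]
            w_slab = (
                probs.exposure_free[:, g, q, :]
                if probs.exposure_free is not None
                else np.ones_like(slab)
            )
            out.p_inc[:, g, q, t_at] = _aligned_base(
                slab, w_slab, probs.years, slopes[g, q], at_year, window
            )
    out.enforce_terminal_age()
    return out


def hold_incidence_constant(
    probs: TransitionProbabilitySet, at_year: int = 2019
) -> TransitionProbabilitySet:
    """Baseline rule: freeze incidence at its ``at_year`` level for later years."""
    out = probs.copy()
    t0 = out.year_index(at_year)
    for t in range(t0 + 1, len(out.years)):
        out.p_inc[..., t] = out.p_inc[..., t0]
    out.enforce_terminal_age()
    return out


def fit_incidence_trend_scenarioA(
    probs: TransitionProbabilitySet,
    trend_from: int = 2011,
    trend_to: int = 2018,
    exclude: tuple[int, int] | None = (2007, 2010),
    horizon: int = 2040,
    pool_quintiles: bool = True,
    base_window: int = 5,
) -> TransitionProbabilitySet:
    """Scenario A: continue the post-2011 incidence decline to the horizon.

    Log incidence is fit log-linearly over the window (the 2007-2010
    diagnosis-surge years are never used, wherever the window is placed)
    and extrapolated for all years after ``trend_to``, scaling each age
    cell's trend-aligned recent level.  The slope is pooled over ages and,
    by default, over quintiles within gender -- stratum-level series at
    desk-scale register sizes cannot identify slopes of order 1%/year --
    while the levels stay fully stratum-specific.  A rising fitted trend
    is allowed but logged.
    """
    fit_mask = (probs.years >= trend_from) & (probs.years <= trend_to)
    if exclude is not None:
        fit_mask &= ~((probs.years >= exclude[0]) & (probs.years <= exclude[1]))
    if not fit_mask.any():
        raise ValueError("incidence fit window is empty after exclusions")
    out = extend_years(probs, horizon)
    target = out.years[out.years > trend_to]
    ti_target = np.searchsorted(out.years, target)
    slopes = _pooled_incidence_slopes(probs, fit_mask, pool_quintiles=pool_quintiles)

    for g in range(len(GENDERS)):
        for q in range(len(QUINTILES)):
            slab = probs.p_inc[:, g, q, :]
            w_slab = (
                probs.exposure_free[:, g, q, :]
                if probs.exposure_free is not None
                else np.ones_like(slab)
            )
            slope = slopes[g, q]
            mult = np.exp(slope * (target - trend_to))
            base = _aligned_base(slab, w_slab, probs.years, slope, trend_to, base_window)
            proj = np.clip(base[:, None] * mult[None, :], 0.0, 1 - EPS)
            out.p_inc[:, g, q, ti_target] = proj
    out.enforce_terminal_age()
    return out


def enforce_joint_constraint(probs: TransitionProbabilitySet) -> TransitionProbabilitySet:
    """Rescale p_inc and p_m_free proportionally where their sum exceeds 1."""
    out = probs.copy()
    s = out.p_inc + out.p_m_free
    bad = np.isfinite(s) & (s > 1.0)
    if bad.any():
        factor = np.where(bad, 0.999 / s, 1.0)
        out.p_inc = out.p_inc * factor
        out.p_m_free = out.p_m_free * factor
    return out
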