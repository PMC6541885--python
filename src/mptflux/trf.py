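"""Lloyd-Taylor temperature response function (TRF) for ecosystem respiration.

The TRF relates ecosystem respiration (ER) to air temperature,

    ER(Ta) = R_ref * exp( E0 * ( 1/(T_ref - T0) - 1/(Ta - T0) ) ),

with the reference temperature T_ref fixed at 10 deg C and T0 fixed at
-46.02 deg C.  R_ref is the respiration at T_ref (mg CO2 m-2 s-1) and E0 is
the temperature-sensitivity parameter.  E0 appears inside the exponent with
inverse-temperature differences, so it carries units of deg C here.

The module provides the closed form, nonlinear least-squares fitting, the
site-year E0 estimate from short-term (15-day) windows, the 30-day moving
R_ref estimate shifted every 5 days (tracking soil-moisture and phenology
variations the closed form ignores), flux normalization, and delta-method
confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError

T_REF = 10.0
T0 = -46.02
#: literature default temperature sensitivity, used when estimation fails
E0_DEFAULT = 309.0
#: short-term window acceptance bounds for E0 (deg C)
E0_BOUNDS = (30.0, 450.0)

_FIT_BOUNDS_RREF = (1e-9, 100.0)
_FIT_BOUNDS_E0 = (10.0, 600.0)


@dataclass
class TRFParams:
    """Fitted Lloyd-Taylor parameters with fixed T_ref and T0."""

    r_ref: float
    e0: float
    t_ref: float = T_REF
    t0: float = T0
    r_ref_se: float | None = None
    e0_se: float | None = None
    cov: np.ndarray | None = None  # 2x2 (r_ref, e0); zero row/col if e0 fixed
    resid_var: float = 0.0  # residual variance of the fit
    resid_rel_var: float = 0.0  # variance of resid/pred (multiplicative scatter)
    n_fit: int = 0
    n_free: int = 2
    converged: bool = True
    message: str = ""

    def predict(self, ta):
        return lloyd_taylor(ta, self.r_ref, self.e0, self.t_ref, self.t0)


def lloyd_taylor(ta, r_ref, e0, t_ref: float = T_REF, t0: float = T0):
    """Evaluate the Lloyd-Taylor TRF at air temperature ``ta`` (deg C).

    Strictly increasing in ``ta`` on (t0, inf); equals ``r_ref`` at
    ``ta = t_ref``.  Raises for temperatures at or below ``t0``, where the
    form is undefined.
    """
    ta = np.asarray(ta, dtype=float)
    if np.any(ta[~np.isnan(ta)] <= t0):
        raise ValueError(f"air temperature at or below T0 = {t0} deg C")
    out = r_ref * np.exp(e0 * (1.0 / (t_ref - t0) - 1.0 / (ta - t0)))
    if out.ndim == 0:
        return float(out)
    return out


def normalize_flux(nee, er_pred):
    """Measured flux divided by TRF-predicted respiration (dimensionless)."""
    er_pred = np.asarray(er_pred, dtype=float)
    if np.any(er_pred[~np.isnan(er_pred)] <= 0):
        raise ValueError("predicted respiration must be positive")
    out = np.asarray(nee, dtype=float) / er_pred
    if out.ndim == 0:
        return float(out)
    return out


def fit_trf(
    ta,
    nee,
    fix_e0: float | None = None,
    min_points: int = 10,
    min_ta_range: float = 2.0,
) -> TRFParams:
    """Nonlinear least-squares fit of the TRF to (Ta, flux) pairs.

    ``nee`` values are the retained nighttime fluxes interpreted as observed
    ER (efflux positive).  With ``fix_e0`` only ``r_ref`` is free.  Standard
    errors come from the Jacobian at the solution.  Non-convergence yields a
    flagged result (``converged=False``) rather than an exception.
    """
    ta = np.asarray(ta, dtype=float)
    nee = np.asarray(nee, dtype=float)
    ok = np.isfinite(ta) & np.isfinite(nee)
    ta, nee = ta[ok], nee[ok]
    n = len(ta)
    if n < min_points:
        raise InsufficientDataError(f"{n} usable (Ta, flux) pairs < {min_points}")
    if fix_e0 is None and np.ptp(ta) < min_ta_range:
        raise InsufficientDataError(
            f"Ta range {np.ptp(ta):.2f} deg C too narrow to identify E0"
        )

    r0 = float(np.clip(np.nanmean(nee), 1e-3, 50.0))
    try:
        if fix_e0 is None:
            popt, pcov = optimize.curve_fit(
                lambda t, r, e: lloyd_taylor(t, r, e),
                ta,
                nee,
                p0=(r0, E0_DEFAULT),
                bounds=(
                    (_FIT_BOUNDS_RREF[0], _FIT_BOUNDS_E0[0]),
                    (_FIT_BOUNDS_RREF[1], _FIT_BOUNDS_E0[1]),
                ),
                method="trf",
                maxfev=5000,
            )
            r_ref, e0 = popt
            cov = np.asarray(pcov, dtype=float)
            n_free = 2
        else:
            popt, pcov = optimize.curve_fit(
                lambda t, r: lloyd_taylor(t, r, fix_e0),
                ta,
                nee,
                p0=(r0,),
                bounds=((_FIT_BOUNDS_RREF[0],), (_FIT_BOUNDS_RREF[1],)),
                method="trf",
                maxfev=5000,
            )
            r_ref, e0 = float(popt[0]), float(fix_e0)
            cov = np.zeros((2, 2))
            cov[0, 0] = float(pcov[0, 0])
            n_free = 1
    except RuntimeError as exc:  # optimizer did not converge
        return TRFParams(
            r_ref=r0,
            e0=fix_e0 if fix_e0 is not None else E0_DEFAULT,
            n_fit=n,
            n_free=2 if fix_e0 is None else 1,
            converged=False,
            message=str(exc),
        )

    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    pred = lloyd_taylor(ta, float(r_ref), float(e0))
    resid = nee - pred
    rel = resid / pred
    dof = max(n - n_free, 1)
    return TRFParams(
        r_ref=float(r_ref),
        e0=float(e0),
        r_ref_se=float(se[0]),
        e0_se=float(se[1]) if fix_e0 is None else 0.0,
        cov=cov,
        resid_var=float(resid @ resid / dof),
        resid_rel_var=float(rel @ rel / dof),
        n_fit=n,
        n_free=n_free,
    )


@dataclass
class E0Estimate:
    """Site-year temperature sensitivity from short-term windows."""

    e0: float
    fallback: bool
    n_windows_accepted: int
    window_e0: list = field(default_factory=list)


def estimate_e0_site_year(
    night: pd.DataFrame,
    window_days: int = 15,
    step_days: int = 5,
    min_points: int = 6,
    min_ta_range: float = 5.0,
) -> E0Estimate:
    """Constant site-year E0 from short-term temperature sensitivity.

    Slides ``window_days`` windows in ``step_days`` steps over the retained
    nighttime data, fits both TRF parameters per window, and accepts windows
    with at least ``min_points`` pairs, a Ta range of at least
    ``min_ta_range`` deg C and E0 within the admissible bounds.  The
    site-year value is the mean of the three accepted estimates with the
    smallest relative standard error; if no window is accepted the literature
    default (309 deg C) is returned with ``fallback=True``.

    ``night`` needs a DatetimeIndex and ``ta``/``nee`` columns.
    """
    accepted: list[tuple[float, float]] = []  # (rel_se, e0)
    if len(night):
        start = night.index[0].normalize()
        stop = night.index[-1]
        t = start
        while t <= stop:
            sub = night[(night.index > t) & (night.index <= t + pd.Timedelta(days=window_days))]
            t += pd.Timedelta(days=step_days)
            ta = sub["ta"].to_numpy(float)
            nee = sub["nee"].to_numpy(float)
            ok = np.isfinite(ta) & np.isfinite(nee)
            if ok.sum() < min_points or np.ptp(ta[ok]) < min_ta_range:
                continue
            try:
                p = fit_trf(ta[ok], nee[ok], min_points=min_points)
            except InsufficientDataError:
                continue
            if not p.converged or p.e0_se is None or not np.isfinite(p.e0_se):
                continue
            if not (E0_BOUNDS[0] <= p.e0 <= E0_BOUNDS[1]) or p.e0_se <= 0:
                continue
            accepted.append((p.e0_se / p.e0, p.e0))

    if not accepted:
        return E0Estimate(e0=E0_DEFAULT, fallback=True, n_windows_accepted=0)
    accepted.sort(key=lambda pair: pair[0])
    best = [e for _, e in accepted[:3]]
    return E0Estimate(
        e0=float(np.mean(best)),
        fallback=False,
        n_windows_accepted=len(accepted),
        window_e0=[e for _, e in accepted],
    )


@dataclass
class RrefSeries:
    """Daily reference-respiration values from a moving-window fit."""

    daily: pd.Series  # DatetimeIndex (midnight), r_ref per day
    centers: pd.Series  # window-center dates -> fitted r_ref
    n_fit: pd.Series  # window-center dates -> points used

    def at(self, timestamps) -> np.ndarray:
        """R_ref for each timestamp (nearest day, so edges extrapolate flat)."""
        days = pd.DatetimeIndex(timestamps).normalize()
        return self.daily.reindex(days, method="nearest").to_numpy(float)


def estimate_rref_moving(
    night: pd.DataFrame,
    e0: float,
    window_days: int = 30,
    step_days: int = 5,
    min_points: int = 6,
) -> RrefSeries:
    """R_ref on a daily grid from 30-day windows shifted every 5 days.

    Each window yields a one-parameter fit (E0 held at the site-year value)
    on the retained nighttime data; daily values are linear interpolations
    between window centers.  Windows with fewer than ``min_points`` pairs
    inherit the nearest valid window's value.
    """
    if not len(night):
        raise InsufficientDataError("no nighttime records for R_ref estimation")
    start = night.index[0].normalize()
    stop = night.index[-1]
    half = pd.Timedelta(days=window_days / 2)
    centers = pd.date_range(start + half, max(stop - half, start + half), freq=f"{step_days}D")
    if not len(centers):
        centers = pd.DatetimeIndex([start + (stop - start) / 2]).normalize()

    values, counts = [], []
    for c in centers:
        sub = night[(night.index > c - half) & (night.index <= c + half)]
        ta = sub["ta"].to_numpy(float)
        nee = sub["nee"].to_numpy(float)
        ok = np.isfinite(ta) & np.isfinite(nee)
        counts.append(int(ok.sum()))
        if ok.sum() < min_points:
            values.append(np.nan)
            continue
        p = fit_trf(ta[ok], nee[ok], fix_e0=e0, min_points=min_points)
        values.append(p.r_ref if p.converged else np.nan)

    center_series = pd.Series(values, index=centers)
    if center_series.notna().sum() == 0:
        raise InsufficientDataError("no moving window had enough data for R_ref")
    # invalid windows inherit the nearest valid window's value
    valid = center_series.dropna()
    filled = center_series.copy()
    for c in center_series.index[center_series.isna()]:
        filled[c] = valid.iloc[np.abs(valid.index - c).argmin()]

    days = pd.date_range(start, stop.normalize(), freq="D")
    daily = (
        filled.reindex(filled.index.union(days))
        .interpolate(method="time")
        .bfill()
        .ffill()
        .reindex(days)
    )
    return RrefSeries(
        daily=daily,
        centers=filled,
        n_fit=pd.Series(counts, index=centers),
    )


def _band(params: TRFParams, ta, level: float, relative_extra_var: float):
    if params.cov is None:
        raise ValueError("fit does not carry parameter standard errors")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ta = np.asarray(ta, dtype=float)
    pred = params.predict(ta)
    # gradient of the closed form w.r.t. (r_ref, e0)
    g_r = pred / params.r_ref
    g_e = pred * (1.0 / (params.t_ref - params.t0) - 1.0 / (ta - params.t0))
    grad = np.stack([g_r, g_e], axis=-1)
    var = np.einsum("...i,ij,...j->...", grad, params.cov, grad)
    se = np.sqrt(np.clip(var + relative_extra_var * pred**2, 0.0, np.inf))
    df = max(params.n_fit - params.n_free, 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    return pred - tq * se, pred + tq * se


def trf_confidence_band(params: TRFParams, ta, level: float = 0.95):
    """Pointwise confidence band for the mean TRF curve.

    First-order (delta-method) propagation of the fitted-parameter
    covariance through the closed form, with a Student-t quantile at
    ``n_fit - n_free`` degrees of freedom.  Returns ``(lower, upper)``.
    """
    return _band(params, ta, level, relative_extra_var=0.0)


def trf_prediction_band(params: TRFParams, ta, level: float = 0.95):
    """Pointwise prediction band for a new observation.

    Adds the fit's observation scatter to the parameter uncertainty, so the
    band covers where individual (noisy) respiration observations are
    expected to fall, not just the mean curve.  The scatter term scales
    with the predicted flux, matching the multiplicative error character of
    nighttime eddy-covariance data.
    """
    return _band(params, ta, level, relative_extra_var=params.resid_rel_var)
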