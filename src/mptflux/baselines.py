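"""Traditional nighttime-correction methods used for comparison.

Three methods accompany the modified moving point test:

* **FVF** — fixed friction-velocity filtering: reject night records with
  u* below a constant threshold (0.3 m s-1 at the reference sites).
* **LRC** — light-response-curve method: daytime ER is the zero-light
  intercept of a Michaelis-Menten light response fitted to daytime flux
  versus incoming shortwave radiation over a 30-day moving window.
* **VGF** — modified van Gorsel method: the peak of the median diurnal
  flux cycle near sunset (R_max), before drainage develops, serves as the
  ER observation, again over a 30-day moving window.

LRC and VGF additionally filter observed night fluxes that fall below the
lower 95% confidence bound of the fitted respiration model (underestimation
only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import InsufficientDataError
from .flux_io import QC_OBSERVED, FluxSeries
from .drainage import REASON_LOW_USTAR, REASON_MISSING, median_diurnal_cycle, find_sunset_peak
from . import trf as _trf

FVF_DEFAULT_THRESHOLD = 0.3


@dataclass
class LRCParams:
    """Michaelis-Menten light-response parameters for one window."""

    r_lrcd: float  # estimated mean daytime ER (y-intercept), mg CO2 m-2 s-1
    alpha_qy: float  # apparent quantum yield, mg CO2 m-2 s-1 per W m-2
    a_max: float  # canopy photosynthetic capacity, mg CO2 m-2 s-1
    center: pd.Timestamp | None = None
    n_fit: int = 0
    converged: bool = True


def fvf_filter(
    series: FluxSeries, threshold: float = FVF_DEFAULT_THRESHOLD
) -> tuple[pd.Series, pd.Series]:
    """Fixed-threshold friction-velocity filter.

    Night records with u* strictly below ``threshold`` (or with missing u*)
    are rejected; daytime records are untouched.  Returns ``(keep, reason)``
    series aligned with the input.
    """
    data = series.data
    night = data["is_night"].to_numpy(bool)
    ustar = data["ustar"].to_numpy(float)
    low = night & (ustar < threshold)
    miss = night & np.isnan(ustar)
    keep = pd.Series(~(low | miss), index=data.index)
    reason = pd.Series("", index=data.index)
    reason[low] = REASON_LOW_USTAR
    reason[miss] = REASON_MISSING
    return keep, reason


def lrc_response(qt, r_lrcd: float, alpha_qy: float, a_max: float):
    """Michaelis-Menten light response: NEE as a function of radiation.

    NEE(Qt) = R_LRCd - alpha*Qt*A_max / (alpha*Qt + A_max); the y-intercept
    R_LRCd is the daytime ER estimate, the saturation limit is
    R_LRCd - A_max.
    """
    qt = np.asarray(qt, dtype=float)
    out = r_lrcd - (alpha_qy * qt * a_max) / (alpha_qy * qt + a_max)
    if out.ndim == 0:
        return float(out)
    return out


def fit_lrc(qt, nee, min_points: int = 50) -> LRCParams:
    """Least-squares fit of the light response to daytime (Qt, NEE) pairs."""
    qt = np.asarray(qt, dtype=float)
    nee = np.asarray(nee, dtype=float)
    ok = np.isfinite(qt) & np.isfinite(nee) & (qt >= 0)
    qt, nee = qt[ok], nee[ok]
    if len(qt) < min_points:
        raise InsufficientDataError(f"{len(qt)} daytime pairs < {min_points}")
    r0 = float(np.clip(np.nanmax(nee), 0.01, 5.0))
    a0 = float(np.clip(r0 - np.nanmin(nee), 0.05, 10.0))
    try:
        popt, _ = optimize.curve_fit(
            lrc_response,
            qt,
            nee,
            p0=(r0, 0.002, a0),
            bounds=((-5.0, 1e-6, 1e-3), (5.0, 1.0, 50.0)),
            method="trf",
            maxfev=5000,
        )
    except RuntimeError:
        return LRCParams(r_lrcd=np.nan, alpha_qy=np.nan, a_max=np.nan,
                         n_fit=len(qt), converged=False)
    return LRCParams(
        r_lrcd=float(popt[0]),
        alpha_qy=float(popt[1]),
        a_max=float(popt[2]),
        n_fit=len(qt),
    )


def lrc_fit_daily(
    series: FluxSeries, window_days: int = 30, min_points: int = 50
) -> pd.DataFrame:
    """Daily daytime-ER estimates from centered 30-day light-response fits.

    Returns a daily DataFrame with columns ``r_lrcd``, ``alpha_qy``,
    ``a_max``, ``ta_day`` (mean daytime air temperature of the window) and
    ``n_fit``.  Days whose fit fails are interpolated from neighbours.
    """
    data = series.data
    day = data[~data["is_night"].astype(bool) & (data["qc"] == QC_OBSERVED)]
    if not len(day):
        raise InsufficientDataError("no observed daytime records")
    half = pd.Timedelta(days=window_days / 2)
    days = pd.date_range(
        data.index[0].normalize(), data.index[-1].normalize(), freq="D"
    )
    rows = []
    for d in days:
        sub = day[(day.index > d - half) & (day.index <= d + half + pd.Timedelta(days=1))]
        try:
            p = fit_lrc(sub["rg"], sub["nee"], min_points=min_points)
        except InsufficientDataError:
            p = LRCParams(np.nan, np.nan, np.nan, converged=False)
        rows.append(
            {
                "r_lrcd": p.r_lrcd if p.converged else np.nan,
                "alpha_qy": p.alpha_qy,
                "a_max": p.a_max,
                "ta_day": float(sub["ta"].mean()) if len(sub) else np.nan,
                "n_fit": p.n_fit,
            }
        )
    table = pd.DataFrame(rows, index=days)
    if table["r_lrcd"].notna().sum() == 0:
        raise InsufficientDataError("no light-response window converged")
    table["r_lrcd"] = table["r_lrcd"].interpolate().bfill().ffill()
    return table


def vgf_rmax_daily(
    series: FluxSeries,
    window_days: int = 30,
    search_window: tuple[float, float] = (15.0, 22.0),
    min_days: int = 7,
) -> pd.DataFrame:
    """Daily sunset-peak respiration observations (R_max) for the VGF method.

    For each day, the median diurnal cycle over the centered 30-day window
    is computed, the near-sunset peak located, and its value returned as the
    day's R_max, paired with the median air temperature of the peak slot.
    Days without a resolvable peak are absent from the result.
    """
    data = series.data
    half = pd.Timedelta(days=window_days / 2)
    span_days = (data.index[-1] - data.index[0]).days + 1
    if span_days < min_days:
        raise InsufficientDataError(f"{span_days} days of data < {min_days}")
    days = pd.date_range(
        data.index[0].normalize(), data.index[-1].normalize(), freq="D"
    )
    rows, idx = [], []
    for d in days:
        sub = data[(data.index > d - half) & (data.index <= d + half + pd.Timedelta(days=1))]
        try:
            cycle = median_diurnal_cycle(sub, min_days=min_days)
            t_peak, _ = find_sunset_peak(cycle, search_window)
        except InsufficientDataError:
            continue
        slot = int(round(t_peak / 0.5)) - 1
        tod = sub.index.hour + sub.index.minute / 60.0
        tod = np.where(tod == 0.0, 24.0, tod)
        at_peak = sub[np.isclose(tod, t_peak)]
        ta_peak = float(at_peak["ta"].median()) if len(at_peak) else np.nan
        rows.append(
            {"r_max": float(cycle.median[slot]), "t_peak": t_peak, "ta": ta_peak}
        )
        idx.append(d)
    if not rows:
        raise InsufficientDataError("no day yielded a sunset peak")
    return pd.DataFrame(rows, index=pd.DatetimeIndex(idx))


def ci_underestimation_filter(
    night: pd.DataFrame, trf_fit: _trf.TRFParams, level: float = 0.95
) -> pd.Series:
    """Keep-mask rejecting night fluxes below the ER model's confidence band.

    One-sided: a record is rejected only when its flux falls below the lower
    bound of the ``level`` prediction band at the record's temperature —
    i.e. it is underestimated beyond what the fitted respiration model and
    its observation scatter allow.  Records with missing flux or temperature
    are kept (they carry no evidence either way).
    """
    ta = night["ta"].to_numpy(float)
    nee = night["nee"].to_numpy(float)
    ok = np.isfinite(ta) & np.isfinite(nee)
    keep = np.ones(len(night), dtype=bool)
    if ok.any():
        lower, _ = _trf.trf_prediction_band(trf_fit, ta[ok], level=level)
        keep[np.flatnonzero(ok)[nee[ok] < lower]] = False
    return pd.Series(keep, index=night.index)
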