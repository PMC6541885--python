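"""End-to-end nighttime correction: thresholds -> filter -> TRF -> fill -> budget.

This is the glue the CLI and the method-comparison reports use.  Each
correction method yields a keep/reject mask over the nighttime records; the
retained records (or, for the LRC and VGF baselines, the daily ER
observations) feed the site-year E0 estimate and the moving-window R_ref;
rejected and missing night fluxes are replaced by TRF predictions; daytime
ER is extrapolated from the nighttime relationship; and NEE is partitioned
into GPP and ER.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from . import flux_io
from .flux_io import QC_OBSERVED, FluxSeries, Period, split_periods
from . import baselines as _baselines
from . import drainage as _drainage
from . import mpt as _mpt
from . import partition_ops as _partition
from . import trf as _trf

METHODS = ("mpt", "fvf", "lrc", "vgf")


@dataclass
class CorrectionResult:
    method: str
    keep: pd.Series
    reason: pd.Series
    partitioned: pd.DataFrame
    budget: _partition.AnnualBudget | None
    e0: _trf.E0Estimate | None
    rref: _trf.RrefSeries | None
    gapfill: _partition.GapfillReport | None
    period_results: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def detect_thresholds(
    series: FluxSeries,
    mpt_config: _mpt.MPTConfig | None = None,
    **modified_kwargs,
) -> tuple[list[_drainage.PeriodResult], list[tuple[Period, str]]]:
    """Modified MPT per quarter; failed periods are reported, not fatal."""
    results, errors = [], []
    for period, sub in split_periods(series):
        if not len(sub):
            continue
        try:
            res = _drainage.run_modified_mpt(
                sub, period=None, mpt_config=mpt_config, **modified_kwargs
            )
            res.period = period
            results.append(res)
        except InsufficientDataError as exc:
            errors.append((period, str(exc)))
    return results, errors


def _mask_mpt(series, mpt_config, flags, **kw):
    results, errors = detect_thresholds(series, mpt_config, **kw)
    keep = pd.Series(True, index=series.data.index)
    reason = pd.Series("", index=series.data.index)
    for res in results:
        keep.loc[res.keep.index] = res.keep
        reason.loc[res.reason.index] = res.reason
    for period, msg in errors:
        flags.append(f"period {period.label}: {msg}; fixed-threshold fallback")
        doy = flux_io.effective_doy(series.data.index)
        in_p = period.contains(doy)
        fb_keep, fb_reason = _baselines.fvf_filter(series)
        keep[in_p] = fb_keep[in_p].to_numpy()
        reason[in_p] = fb_reason[in_p].to_numpy()
    return keep, reason, results


def _daily_er_observations(series, method, flags):
    """Daily (Ta, ER) pairs from the LRC or VGF baselines."""
    if method == "lrc":
        table = _baselines.lrc_fit_daily(series)
        obs = pd.DataFrame(
            {"ta": table["ta_day"].to_numpy(), "nee": table["r_lrcd"].to_numpy()},
            index=table.index + pd.Timedelta(hours=12),
        )
    else:
        table = _baselines.vgf_rmax_daily(series)
        obs = pd.DataFrame(
            {"ta": table["ta"].to_numpy(), "nee": table["r_max"].to_numpy()},
            index=table.index + pd.Timedelta(hours=12),
        )
    obs = obs.dropna()
    if len(obs) < 6:
        raise InsufficientDataError(f"{method}: only {len(obs)} daily ER observations")
    return obs


def correct(
    series: FluxSeries,
    method: str = "mpt",
    mpt_config: _mpt.MPTConfig | None = None,
    fvf_threshold: float = _baselines.FVF_DEFAULT_THRESHOLD,
    ci_level: float = 0.95,
    compute_budget: bool | None = None,
    **modified_kwargs,
) -> CorrectionResult:
    """Run one nighttime-correction method end to end.

    ``method`` is one of ``mpt`` (modified moving point test), ``fvf``
    (fixed u* threshold), ``lrc`` or ``vgf``.  The budget is computed when
    the series covers (nearly) a full year, or when ``compute_budget`` is
    forced True.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    flags: list[str] = []
    data = series.data
    night = data["is_night"].astype(bool)
    period_results: list = []

    if method == "mpt":
        keep, reason, period_results = _mask_mpt(series, mpt_config, flags, **modified_kwargs)
    elif method == "fvf":
        keep, reason = _baselines.fvf_filter(series, fvf_threshold)
    else:
        keep = pd.Series(True, index=data.index)
        reason = pd.Series("", index=data.index)

    # observations feeding the respiration model
    if method in ("mpt", "fvf"):
        retained = data[
            night & keep & (data["qc"] == QC_OBSERVED)
            & data["nee"].notna() & data["ta"].notna()
        ]
        fit_source = retained[["ta", "nee"]]
    else:
        fit_source = _daily_er_observations(series, method, flags)

    e0 = _trf.estimate_e0_site_year(fit_source)
    if e0.fallback:
        flags.append("E0 estimation fell back to the 309 deg C default")
    rref = _trf.estimate_rref_moving(fit_source, e0.e0)

    if method in ("lrc", "vgf"):
        # reject observed night fluxes underestimated beyond the CI of the model
        band_fit = _trf.fit_trf(
            fit_source["ta"], fit_source["nee"], fix_e0=e0.e0, min_points=6
        )
        night_df = data[night]
        ci_keep = _baselines.ci_underestimation_filter(night_df, band_fit, level=ci_level)
        keep.loc[ci_keep.index[~ci_keep]] = False
        reason.loc[ci_keep.index[~ci_keep]] = "below_ci"

    filled, report = _partition.gapfill_nighttime(series, keep, e0.e0, rref)
    er_model = _partition.estimate_daytime_er(series, e0.e0, rref)
    part = _partition.partition(filled, er_model)

    if compute_budget is None:
        n_days = (data.index[-1] - data.index[0]).days + 1
        compute_budget = n_days >= 360
    budget = _partition.annual_budget(part) if compute_budget else None

    return CorrectionResult(
        method=method,
        keep=keep,
        reason=reason,
        partitioned=part,
        budget=budget,
        e0=e0,
        rref=rref,
        gapfill=report,
        period_results=period_results,
        flags=flags,
    )


def compare_methods(
    series: FluxSeries,
    methods=METHODS,
    **kwargs,
) -> pd.DataFrame:
    """Budgets from several correction methods, one row per method."""
    rows = {}
    for m in methods:
        res = correct(series, method=m, compute_budget=True, **kwargs)
        rows[m] = res.budget.as_dict()
    return pd.DataFrame(rows).T
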