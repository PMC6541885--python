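"""Gap-filling of rejected nighttime fluxes and NEE partitioning.

Rejected or missing nighttime records are replaced by the Lloyd-Taylor
prediction at the record's air temperature, using the daily moving-window
R_ref and the constant site-year E0.  The nighttime respiration-temperature
relationship is extrapolated to daytime to estimate daytime ER, and
GPP = ER - NEE.  Annual budgets integrate the half-hourly series to
g C m-2 yr-1 (negative NEE = net uptake).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FluxDataError
from .flux_io import QC_FILLED, QC_MISSING, QC_OBSERVED, FluxSeries
from . import trf as _trf

#: g C per g CO2
C_PER_CO2 = 12.011 / 44.009
#: seconds per half-hour record
SECONDS_PER_RECORD = 1800.0


@dataclass
class GapfillReport:
    n_filled: int = 0
    n_unfillable: int = 0
    unfillable: list = field(default_factory=list)


def _interpolate_ta(data: pd.DataFrame, max_gap_hours: float = 3.0) -> pd.Series:
    limit = int(max_gap_hours * 2)
    return data["ta"].interpolate(method="time", limit=limit, limit_area="inside")


def gapfill_nighttime(
    series: FluxSeries,
    keep: pd.Series,
    e0: float,
    rref: _trf.RrefSeries,
) -> tuple[pd.DataFrame, GapfillReport]:
    """Replace rejected/missing nighttime fluxes with TRF estimates.

    Returns a copy of the series frame with ``nee_filled`` and updated
    ``qc`` (``filled`` where a value was replaced).  Air temperature is
    interpolated across gaps up to 3 h; records that still lack Ta remain
    missing and are counted in the report, never silently dropped.
    """
    data = series.data.copy()
    night = data["is_night"].to_numpy(bool)
    keep = keep.reindex(data.index, fill_value=True).to_numpy(bool)
    needs_fill = night & (~keep | data["nee"].isna().to_numpy())

    ta = _interpolate_ta(data)
    r_ref_day = rref.at(data.index)
    can_fill = needs_fill & ta.notna().to_numpy() & np.isfinite(r_ref_day)

    nee_filled = data["nee"].to_numpy(float).copy()
    nee_filled[needs_fill] = np.nan
    fill_vals = _trf.lloyd_taylor(
        ta.to_numpy(float)[can_fill], r_ref_day[can_fill], e0
    )
    nee_filled[can_fill] = fill_vals

    qc = data["qc"].to_numpy(object).copy()
    qc[can_fill] = QC_FILLED
    unfillable = needs_fill & ~can_fill
    qc[unfillable] = QC_MISSING

    data["nee_filled"] = nee_filled
    data["qc"] = qc
    report = GapfillReport(
        n_filled=int(can_fill.sum()),
        n_unfillable=int(unfillable.sum()),
        unfillable=list(data.index[unfillable]),
    )
    return data, report


def estimate_daytime_er(
    series: FluxSeries, e0: float, rref: _trf.RrefSeries
) -> pd.Series:
    """Daytime ER by extrapolating the nighttime TRF to daytime temperature."""
    data = series.data
    ta = _interpolate_ta(data)
    r_ref_day = rref.at(data.index)
    er = np.full(len(data), np.nan)
    ok = ta.notna().to_numpy() & np.isfinite(r_ref_day)
    er[ok] = _trf.lloyd_taylor(ta.to_numpy(float)[ok], r_ref_day[ok], e0)
    return pd.Series(er, index=data.index, name="er")


def partition(filled: pd.DataFrame, er_model: pd.Series) -> pd.DataFrame:
    """Split NEE into ER and GPP (GPP = ER - NEE).

    Nighttime ER is the (observed or filled) nighttime flux itself, so
    nighttime GPP is zero by construction; daytime ER comes from the
    extrapolated respiration model.
    """
    if "nee_filled" not in filled.columns:
        raise FluxDataError("run gapfill_nighttime first (no nee_filled column)")
    out = filled.copy()
    night = out["is_night"].to_numpy(bool)
    er = er_model.reindex(out.index).to_numpy(float)
    nee = out["nee_filled"].to_numpy(float)
    er_final = np.where(night, nee, er)
    gpp = np.where(night, 0.0, er_final - nee)
    gpp[np.isnan(nee)] = np.nan
    out["er"] = er_final
    out["gpp"] = gpp
    return out


@dataclass
class AnnualBudget:
    """Annual sums in g C m-2 yr-1 (NEE negative = uptake)."""

    nee: float
    gpp: float
    er: float
    filled_night_fraction: float
    n_records: int

    def as_dict(self) -> dict:
        return {
            "nee_gC_m2": self.nee,
            "gpp_gC_m2": self.gpp,
            "er_gC_m2": self.er,
            "filled_night_fraction": self.filled_night_fraction,
            "n_records": self.n_records,
        }


def integrate(values: np.ndarray) -> float:
    """Half-hourly mg CO2 m-2 s-1 series -> g C m-2 over the series."""
    return float(np.sum(values) * SECONDS_PER_RECORD * C_PER_CO2 / 1000.0)


def annual_budget(partitioned: pd.DataFrame, year: int | None = None) -> AnnualBudget:
    """Annual NEE / GPP / ER sums from a fully resolved partitioned series.

    Every record must be observed or filled; unresolved records are a hard
    error (listing them) because a budget over a gappy series is silently
    biased.
    """
    df = partitioned
    if year is not None:
        df = df[df.index.year == year]
    bad = df.index[df["nee_filled"].isna() | df["er"].isna()]
    if len(bad):
        head = ", ".join(str(t) for t in bad[:5])
        raise FluxDataError(
            f"{len(bad)} unresolved records (first: {head}); "
            "fill or drop them before computing a budget"
        )
    night = df["is_night"].to_numpy(bool)
    filled = (df["qc"] == QC_FILLED).to_numpy(bool)
    frac = float(filled[night].mean()) if night.any() else 0.0
    return AnnualBudget(
        nee=integrate(df["nee_filled"].to_numpy(float)),
        gpp=integrate(df["gpp"].to_numpy(float)),
        er=integrate(df["er"].to_numpy(float)),
        filled_night_fraction=frac,
        n_records=len(df),
    )
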