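"""Half-hourly flux series data model, CSV readers/writers and segmentation.

A flux series is a :class:`pandas.DataFrame` wrapped in :class:`FluxSeries`,
with one row per half hour on a strict 30-minute grid.  Timestamps label the
END of each averaging interval, in local standard time (no DST shifts).  The
standard columns are

===========  ==================================================================
``nee``      net ecosystem CO2 exchange, mg CO2 m-2 s-1 (eddy + storage),
             negative = uptake
``ustar``    friction velocity, m s-1
``ta``       air temperature, deg C
``rg``       incoming shortwave radiation, W m-2
``is_night`` boolean nighttime flag (``rg`` below a threshold, default 10)
``qc``       one of ``observed | missing | filtered | filled``
===========  ==================================================================

Missing values are encoded as -9999 on disk and as NaN in memory; gaps in the
time grid are represented as rows with ``qc = "missing"``, never as absent
rows.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FluxDataError

#: on-disk missing-value sentinel
MISSING_SENTINEL = -9999.0
#: sentinel printed for "no upper u* threshold determined"
NO_UPPER_SENTINEL = 9999.0

QC_OBSERVED = "observed"
QC_MISSING = "missing"
QC_FILTERED = "filtered"
QC_FILLED = "filled"

#: default mapping from standard column names to CSV column names
DEFAULT_COLUMN_MAP = {
    "timestamp": "timestamp",
    "nee": "nee",
    "ustar": "ustar",
    "ta": "ta",
    "rg": "rg",
    "cov_uw": "cov_uw",
    "cov_vw": "cov_vw",
    "storage": "storage",
}

_CORE_COLUMNS = ["nee", "ustar", "ta", "rg"]


def ustar_from_covariances(cov_uw, cov_vw):
    """Friction velocity from the two momentum covariances.

    u* = (u'w'^2 + v'w'^2)^(1/4), in m s-1.  Missing covariances propagate
    to a missing result; the value is invariant to the covariance signs and
    to swapping the two components.
    """
    cov_uw = np.asarray(cov_uw, dtype=float)
    cov_vw = np.asarray(cov_vw, dtype=float)
    out = (cov_uw**2 + cov_vw**2) ** 0.25
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class FluxSeries:
    """A site-year (or shorter) half-hourly flux series."""

    data: pd.DataFrame
    site: str = "site"
    year: int | None = None
    rg_night_threshold: float = 10.0

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FluxDataError("FluxSeries index must be a DatetimeIndex")
        if idx.has_duplicates:
            raise FluxDataError("duplicate timestamps in flux series")
        if len(idx) > 1:
            deltas = np.diff(idx.view("int64"))
            if not np.all(deltas == 30 * 60 * 10**9):
                raise FluxDataError(
                    "timestamps must be strictly increasing on a 30-min grid"
                )
        if self.year is None and len(idx):
            self.year = int(idx[-1].year)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def night(self) -> pd.DataFrame:
        """Records flagged as nighttime."""
        return self.data[self.data["is_night"].astype(bool)]

    def copy(self) -> "FluxSeries":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class Period:
    """A contiguous day-of-year range (inclusive on both ends)."""

    label: str
    doy_start: int
    doy_end: int

    def contains(self, doy) -> np.ndarray:
        doy = np.asarray(doy)
        return (doy >= self.doy_start) & (doy <= self.doy_end)


def effective_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day of year each interval belongs to (midnight ends close the day)."""
    return (index - pd.Timedelta(minutes=1)).dayofyear.to_numpy()


def quarters(year: int) -> list[Period]:
    """The four three-month periods used for threshold detection.

    DOY 1-90, 91-181, 182-273 and 274-365 (366 in leap years).
    """
    last = 366 if calendar.isleap(year) else 365
    bounds = [(1, 90), (91, 181), (182, 273), (274, last)]
    return [Period(f"{a}-{b}", a, b) for a, b in bounds]


def _resolve_columns(header: Sequence[str], column_map: dict | None) -> dict:
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    return {std: col for std, col in cmap.items() if col in header}


def read_halfhourly_csv(
    path,
    column_map: dict | None = None,
    missing_sentinel: float = MISSING_SENTINEL,
    site: str = "site",
    rg_night_threshold: float = 10.0,
) -> FluxSeries:
    """Read a half-hourly delimited-text flux file into a :class:`FluxSeries`.

    Parameters
    ----------
    path
        CSV file with one row per half hour.
    column_map
        Mapping from standard names (``timestamp``, ``nee``, ``ustar``, ``ta``,
        ``rg``, optionally ``cov_uw``, ``cov_vw``, ``storage``) to the file's
        column names.  Unmapped names fall back to the standard names.
    missing_sentinel
        Numeric value treated as missing (default -9999); empty cells are
        missing as well.

    If ``ustar`` is absent but both momentum covariances are present, u* is
    computed from them.  If a ``storage`` column is mapped, it is added to
    ``nee`` (for files that store the eddy and storage terms separately).
    Gaps in the 30-minute grid are inserted as rows with ``qc = "missing"``.
    """
    raw = pd.read_csv(path)
    cols = _resolve_columns(list(raw.columns), column_map)
    if "timestamp" not in cols:
        raise FluxDataError(f"{path}: no timestamp column (have {list(raw.columns)})")

    ts = pd.to_datetime(raw[cols["timestamp"]], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise FluxDataError(
            f"{path}: unparseable timestamp at data row {row}: "
            f"{raw[cols['timestamp']].iloc[row]!r}"
        )
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise FluxDataError(f"{path}: timestamps not strictly increasing")

    df = pd.DataFrame(index=pd.DatetimeIndex(ts.values, name="timestamp"))
    for std in ("nee", "ustar", "ta", "rg", "cov_uw", "cov_vw", "storage"):
        if std in cols:
            vals = pd.to_numeric(raw[cols[std]], errors="coerce").to_numpy(float)
            vals[vals == missing_sentinel] = np.nan
            df[std] = vals

    if "ustar" not in df.columns and {"cov_uw", "cov_vw"} <= set(df.columns):
        df["ustar"] = ustar_from_covariances(df["cov_uw"], df["cov_vw"])
    if "storage" in df.columns:
        df["nee"] = df.get("nee", np.nan) + df["storage"]
        df = df.drop(columns=["storage"])

    for col in _CORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    # negative u* cannot be a valid friction velocity
    df.loc[df["ustar"] < 0, "ustar"] = np.nan

    # insert grid gaps as missing records
    full = pd.date_range(df.index[0], df.index[-1], freq="30min", name="timestamp")
    df = df.reindex(full)

    if "qc" in raw.columns:
        qc = raw.set_index(pd.DatetimeIndex(ts.values))["qc"].reindex(full)
        df["qc"] = qc.where(qc.notna(), QC_MISSING)
        df.loc[df["nee"].isna() & (df["qc"] == QC_OBSERVED), "qc"] = QC_MISSING
    else:
        df["qc"] = np.where(df["nee"].notna(), QC_OBSERVED, QC_MISSING)

    had_night = "is_night" in raw.columns
    if had_night:
        isn = raw.set_index(pd.DatetimeIndex(ts.values))["is_night"].reindex(full)
        df["is_night"] = (
            isn.map({True: True, False: False, "True": True, "False": False})
            .fillna(False)
            .astype(bool)
        )
    else:
        df["is_night"] = False

    canonical = ["nee", "ustar", "ta", "rg", "is_night", "qc"]
    extras = [c for c in df.columns if c not in canonical]
    df = df[canonical + extras]

    series = FluxSeries(df, site=site, rg_night_threshold=rg_night_threshold)
    if not had_night:
        series = flag_night(series, rg_night_threshold)
    return series


def flag_night(series: FluxSeries, rg_threshold: float | None = None) -> FluxSeries:
    """Flag nighttime records: ``rg`` strictly below ``rg_threshold`` (W m-2).

    Records with missing ``rg`` inherit the flag of the nearest observed
    record at the same time of day.
    """
    if rg_threshold is None:
        rg_threshold = series.rg_night_threshold
    df = series.data.copy()
    rg = df["rg"]
    if rg.isna().all():
        raise FluxDataError("cannot flag night: all rg values missing")
    night = rg < rg_threshold

    if rg.isna().any():
        tod = df.index.hour * 60 + df.index.minute
        filled = night.copy()
        for slot, grp in night[rg.notna()].groupby(tod[rg.notna()]):
            holes = rg.isna() & (tod == slot)
            if holes.any():
                pos = grp.index.view("int64")
                want = df.index[holes].view("int64")
                nearest = np.abs(want[:, None] - pos[None, :]).argmin(axis=1)
                filled[holes] = grp.to_numpy()[nearest]
        # slots never observed: fall back to the overall nearest observation
        still = rg.isna() & ~np.isin(tod, np.unique(tod[rg.notna()]))
        if still.any():
            obs = night[rg.notna()]
            pos = obs.index.view("int64")
            want = df.index[still].view("int64")
            nearest = np.abs(want[:, None] - pos[None, :]).argmin(axis=1)
            filled[still] = obs.to_numpy()[nearest]
        night = filled
    df["is_night"] = night.astype(bool)
    out = replace(series, data=df, rg_night_threshold=rg_threshold)
    return out


def split_periods(
    series: FluxSeries, year: int | None = None
) -> list[tuple[Period, FluxSeries]]:
    """Slice a series into the four quarter periods by interval-end DOY."""
    if year is None:
        year = series.year
    if year is None:
        raise FluxDataError("year required to split periods")
    out = []
    # a record ending exactly at midnight belongs to the day it measured
    doy = effective_doy(series.data.index)
    in_year = (series.data.index - pd.Timedelta(minutes=1)).year == year
    for period in quarters(year):
        mask = period.contains(doy) & in_year
        sliced = series.data[mask]
        if len(sliced):
            sub = replace(series, data=sliced)
        else:
            sub = replace(series, data=series.data.iloc[0:0])
        out.append((period, sub))
    return out


_FLOAT_FMT = "%.6f"


def write_halfhourly_csv(series: FluxSeries, path) -> None:
    """Write a series in the package's CSV dialect (-9999 for missing)."""
    df = series.data.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].fillna(MISSING_SENTINEL)
    df.index.name = "timestamp"
    df.to_csv(path, float_format=_FLOAT_FMT, date_format="%Y-%m-%d %H:%M")


def _fmt_threshold(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if value == NO_UPPER_SENTINEL:
        return "9999"
    return f"{value:.3f}"


def write_period_report(results: Iterable, path=None) -> pd.DataFrame:
    """Write the per-period threshold/drainage summary table.

    ``results`` is an iterable of period results (see
    :func:`mptflux.drainage.run_modified_mpt`); each row reports the lower and
    upper u* thresholds for the two time windows and whether midnight CO2
    drainage was significant.  An undetermined upper threshold is written with
    the 9999 sentinel, absent values as ``NA``.
    """
    rows = []
    for res in results:
        def thr(mpt, attr):
            if mpt is None:
                return None
            return getattr(mpt, attr)

        rows.append(
            {
                "site": getattr(res, "site", ""),
                "year": getattr(res, "year", ""),
                "doy": f"{res.period.doy_start}-{res.period.doy_end}",
                "ustar_low_w1": _fmt_threshold(thr(res.mpt_w1, "ustar_low")),
                "ustar_high_w1": _fmt_threshold(thr(res.mpt_w1, "ustar_high")),
                "ustar_low_w2": _fmt_threshold(thr(res.mpt_w2, "ustar_low")),
                "ustar_high_w2": _fmt_threshold(thr(res.mpt_w2, "ustar_high")),
                "drainage": "significant" if res.drainage_significant else "negligible",
            }
        )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False)
    return table
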