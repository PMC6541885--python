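"""Synthetic half-hourly flux series with known truth.

The generator emulates the phenomena the nighttime-correction machinery is
built for: a diel (plus optional seasonal) air-temperature cycle driving
Lloyd-Taylor respiration, a Michaelis-Menten light response for daytime
uptake, lognormal friction velocity with a nighttime shift, u*-dependent
suppression of the measured nighttime flux below a known threshold, an
optional post-sunset drainage window in which measured fluxes are further
suppressed despite high u*, an optional high-u* anomaly, heteroscedastic
(multiplicative + additive) noise, and night-only missingness.  The truth
frame carries the unsuppressed flux components so recovery can be scored
exactly.

The default regime is a strong-turbulence site: most nighttime records sit
above the true threshold (the plateau geometry the moving point test
presumes), with both u* strata still populated well beyond the moving-sample
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flux_io import QC_MISSING, QC_OBSERVED, FluxSeries
from . import trf as _trf
from .baselines import lrc_response


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the reference study conditions."""

    n_days: int = 90
    year: int = 2009
    start_doy: int = 1
    site: str = "synthetic"
    seed: int = 0

    # respiration truth
    r_ref: float = 0.2  # mg CO2 m-2 s-1 at 10 deg C
    e0: float = 309.0  # deg C

    # air temperature: diel + optional seasonal cycle
    ta_mean: float = 12.0  # deg C
    ta_amplitude: float = 5.0  # diel half-range
    ta_peak_hour: float = 14.0
    ta_seasonal_amplitude: float = 0.0  # half-range over the year

    # radiation and daytime light response
    rg_max: float = 800.0  # W m-2
    sunrise: float = 6.0
    sunset: float = 18.0
    alpha_qy: float = 0.002  # mg CO2 m-2 s-1 per W m-2
    a_max: float = 1.5  # mg CO2 m-2 s-1

    # friction velocity (lognormal)
    ustar_median_night: float = 0.45  # m s-1
    ustar_median_day: float = 0.55
    ustar_sigma: float = 0.35  # sigma of log u*

    # u*-dependent suppression of measured night flux
    ustar_threshold: float = 0.25  # m s-1
    suppression_factor: float = 1.0  # 1 = no suppression

    # post-sunset drainage window (second time window)
    drainage_enabled: bool = False
    drainage_start_offset: float = 2.0  # hours after the sunset flux peak
    drainage_suppression: float = 0.3

    # high-u* anomaly: moderate flux elevation at the top of the u* range.
    # (a gross, many-sigma elevation would be caught by the 3-sigma outlier
    # rule instead of the upper-threshold scan)
    high_anomaly_enabled: bool = False
    high_anomaly_ustar: float = 0.9
    high_anomaly_factor: float = 1.5

    # noise and missingness
    noise_mult_sd: float = 0.2  # sd of the mean-1 multiplicative factor
    noise_add_sd: float = 0.01  # mg CO2 m-2 s-1
    missing_fraction: float = 0.1  # applied to nighttime records only

    def __post_init__(self) -> None:
        if self.n_days < 7:
            raise ValueError("n_days must be at least 7")
        for name in ("suppression_factor", "drainage_suppression", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[FluxSeries, pd.DataFrame]:
    """Generate a half-hourly series and its truth frame.

    Truth columns: ``er_true``, ``gpp_true``, ``nee_true`` (mg CO2 m-2 s-1,
    NEE = ER - GPP exactly), ``suppressed`` (u* below threshold at night),
    ``window2`` (inside the drainage clock window), ``anomalous``.  The
    measured flux is the true flux times the applicable suppression factors,
    times multiplicative noise, plus additive noise; reproducible from the
    seed.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    start = pd.Timestamp(config.year, 1, 1) + pd.Timedelta(days=config.start_doy - 1)
    index = pd.date_range(
        start + pd.Timedelta(minutes=30),
        periods=config.n_days * 48,
        freq="30min",
        name="timestamp",
    )
    # physics evaluated at the interval midpoint
    tod = (index.hour + index.minute / 60.0).to_numpy() - 0.25
    tod %= 24.0
    frac_year = (index.dayofyear.to_numpy() - 1) / 365.25

    ta = (
        config.ta_mean
        + config.ta_seasonal_amplitude * np.sin(2 * np.pi * (frac_year - 0.25) * 1.0)
        + config.ta_amplitude
        * np.cos(2 * np.pi * (tod - config.ta_peak_hour) / 24.0)
    )

    daylen = config.sunset - config.sunrise
    solar = np.sin(np.pi * np.clip((tod - config.sunrise) / daylen, 0.0, 1.0))
    rg = config.rg_max * np.clip(solar, 0.0, None) ** 1.2
    night = rg < 10.0

    er_true = _trf.lloyd_taylor(ta, config.r_ref, config.e0)
    gpp_true = np.where(night, 0.0, lrc_response(rg, 0.0, config.alpha_qy, config.a_max) * -1.0)
    nee_true = er_true - gpp_true

    mu = np.where(night, np.log(config.ustar_median_night), np.log(config.ustar_median_day))
    ustar = np.exp(rng.normal(mu, config.ustar_sigma))

    suppressed = night & (ustar < config.ustar_threshold)
    factor = np.where(suppressed, config.suppression_factor, 1.0)

    window2 = np.zeros(len(index), dtype=bool)
    if config.drainage_enabled:
        # drainage develops a fixed delay after the evening flux peak, which
        # is the warmest (first) nighttime slot of the diel cycle
        tod_end = (index.hour + index.minute / 60.0).to_numpy()
        tod_end = np.where(tod_end == 0.0, 24.0, tod_end)
        night_slots = np.unique(tod_end[night])
        peak_tod = float(
            night_slots[np.argmax([er_true[night & (tod_end == s)].mean() for s in night_slots])]
        )
        drain_start = peak_tod + config.drainage_start_offset
        window2 = night & ((tod_end > drain_start) | (tod_end <= config.sunrise))
        factor = np.where(window2, factor * config.drainage_suppression, factor)

    anomalous = np.zeros(len(index), dtype=bool)
    if config.high_anomaly_enabled:
        anomalous = night & (ustar >= config.high_anomaly_ustar)
        factor = np.where(anomalous, factor * config.high_anomaly_factor, factor)

    sigma_ln = np.sqrt(np.log1p(config.noise_mult_sd**2))
    mult = rng.lognormal(-(sigma_ln**2) / 2.0, sigma_ln, len(index))
    add = rng.normal(0.0, config.noise_add_sd, len(index))
    nee_meas = nee_true * factor * mult + add

    missing = np.zeros(len(index), dtype=bool)
    if config.missing_fraction > 0:
        night_idx = np.flatnonzero(night)
        k = int(round(config.missing_fraction * len(night_idx)))
        if k:
            missing[rng.choice(night_idx, size=k, replace=False)] = True

    data = pd.DataFrame(
        {
            "nee": np.where(missing, np.nan, nee_meas),
            "ustar": ustar,
            "ta": ta,
            "rg": rg,
            "is_night": night,
            "qc": np.where(missing, QC_MISSING, QC_OBSERVED),
        },
        index=index,
    )
    truth = pd.DataFrame(
        {
            "er_true": er_true,
            "gpp_true": gpp_true,
            "nee_true": nee_true,
            "suppressed": suppressed,
            "window2": window2,
            "anomalous": anomalous,
            "suppression_applied": factor,
        },
        index=index,
    )
    series = FluxSeries(data, site=config.site, year=config.year)
    return series, truth


def scenario_library() -> dict[str, SyntheticConfig]:
    """Named generator configurations for the standard test scenarios."""
    return {
        "no_dependence": SyntheticConfig(suppression_factor=1.0),
        "threshold_only": SyntheticConfig(suppression_factor=0.3),
        "threshold_plus_drainage": SyntheticConfig(
            suppression_factor=0.3,
            drainage_enabled=True,
            drainage_suppression=0.3,
        ),
        "high_ustar_anomaly": SyntheticConfig(
            suppression_factor=1.0, high_anomaly_enabled=True
        ),
        "identity": SyntheticConfig(
            suppression_factor=1.0,
            noise_mult_sd=0.0,
            noise_add_sd=0.0,
            missing_fraction=0.0,
        ),
    }
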