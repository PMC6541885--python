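import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mptflux import (
    InsufficientDataError,
    TRFParams,
    estimate_e0_site_year,
    estimate_rref_moving,
    fit_trf,
    lloyd_taylor,
    normalize_flux,
    trf_confidence_band,
)
from mptflux.trf import E0_DEFAULT, T0


class TestLloydTaylor:
    def test_reference_temperature_returns_r_ref(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r_ref = rng.uniform(0.01, 10.0)
            e0 = rng.uniform(30.0, 450.0)
            assert lloyd_taylor(10.0, r_ref, e0) == pytest.approx(r_ref, abs=1e-12)

    @pytest.mark.parametrize(
        "ta, expected",
        [(20.0, 4.612), (0.0, 0.603)],
    )
    def test_hand_arithmetic(self, ta, expected):
        assert lloyd_taylor(ta, 2.0, 309.0) == pytest.approx(expected, abs=5e-4)

    def test_domain_error_below_t0(self):
        with pytest.raises(ValueError):
            lloyd_taylor(T0 - 1.0, 2.0, 309.0)

    @settings(max_examples=50, deadline=None)
    @given(
        r_ref=st.floats(0.01, 10),
        e0=st.floats(30, 450),
        ta=st.floats(-40, 45),
    )
    def test_strictly_increasing(self, r_ref, e0, ta):
        assert lloyd_taylor(ta + 0.5, r_ref, e0) > lloyd_taylor(ta, r_ref, e0)


class TestNormalize:
    def test_model_matching_observation_is_one(self):
        assert normalize_flux(0.3, 0.3) == pytest.approx(1.0)
        assert normalize_flux(0.0, 0.3) == 0.0
        assert normalize_flux(0.45, 0.3) == pytest.approx(1.5)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            normalize_flux(0.3, 0.0)

    def test_self_normalization_identity(self):
        ta = np.linspace(-5, 25, 50)
        er = lloyd_taylor(ta, 0.7, 250.0)
        assert np.allclose(normalize_flux(er, er), 1.0)


class TestFit:
    def _noiseless(self, r_ref=3.0, e0=250.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        ta = rng.uniform(-5, 25, n)
        return ta, lloyd_taylor(ta, r_ref, e0)

    def test_noiseless_recovery(self):
        ta, er = self._noiseless()
        p = fit_trf(ta, er)
        assert p.r_ref == pytest.approx(3.0, rel=1e-6)
        assert p.e0 == pytest.approx(250.0, rel=1e-6)

    def test_fixed_e0_reduces_to_one_parameter(self):
        ta, er = self._noiseless()
        p = fit_trf(ta, er, fix_e0=250.0)
        assert p.r_ref == pytest.approx(3.0, rel=1e-8)
        assert p.e0 == 250.0
        assert p.n_free == 1

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_trf([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])

    def test_narrow_ta_range_cannot_identify_e0(self):
        ta = np.full(20, 10.0) + np.linspace(0, 0.5, 20)
        with pytest.raises(InsufficientDataError):
            fit_trf(ta, np.ones(20))

    def test_scale_equivariance(self):
        ta, er = self._noiseless()
        for c in (0.5, 4.0):
            p = fit_trf(ta, c * er)
            assert p.r_ref == pytest.approx(c * 3.0, rel=1e-6)
            assert p.e0 == pytest.approx(250.0, rel=1e-5)


def _night_frame(n_days, r_ref, e0, noise_sd, seed, ta_amp=8.0):
    """~10 h of nighttime records per calendar day with a diel+synoptic Ta."""
    rng = np.random.default_rng(seed)
    days = pd.date_range("2009-01-01", periods=n_days, freq="D")
    idx = pd.DatetimeIndex(
        [d + pd.Timedelta(hours=19) + k * pd.Timedelta(minutes=30)
         for d in days for k in range(20)]
    )
    ta = 8.0 + ta_amp * np.sin(np.arange(len(idx)) / 37.0) + rng.normal(0, 1, len(idx))
    er = lloyd_taylor(ta, r_ref, e0)
    nee = er * np.exp(rng.normal(0, noise_sd, len(idx)))
    return pd.DataFrame({"ta": ta, "nee": nee}, index=idx)


class TestE0SiteYear:
    def test_recovery_low_noise(self):
        night = _night_frame(90, r_ref=0.3, e0=200.0, noise_sd=0.05, seed=2)
        est = estimate_e0_site_year(night)
        assert not est.fallback
        assert est.e0 == pytest.approx(200.0, abs=20.0)

    def test_single_window_is_its_own_best_three(self):
        night = _night_frame(14, r_ref=0.3, e0=250.0, noise_sd=0.02, seed=3)
        est = estimate_e0_site_year(night)
        assert est.n_windows_accepted >= 1
        assert est.e0 == pytest.approx(np.mean(est.window_e0[:3]), rel=0.2)

    def test_constant_temperature_falls_back(self):
        night = _night_frame(60, r_ref=0.3, e0=200.0, noise_sd=0.05, seed=4, ta_amp=0.5)
        night["ta"] = 5.0  # no temperature variation at all
        est = estimate_e0_site_year(night)
        assert est.fallback
        assert est.e0 == E0_DEFAULT


class TestRrefMoving:
    def test_stationary_truth_recovered_daily(self):
        night = _night_frame(90, r_ref=3.0, e0=250.0, noise_sd=0.0, seed=5)
        rr = estimate_rref_moving(night, e0=250.0)
        assert np.allclose(rr.daily.to_numpy(), 3.0, rtol=1e-6)

    def test_step_change_transitions_within_window(self):
        night = _night_frame(120, r_ref=1.0, e0=250.0, noise_sd=0.0, seed=6)
        half = night.index < night.index[0] + pd.Timedelta(days=60)
        night.loc[~half, "nee"] *= 2.0
        rr = estimate_rref_moving(night, e0=250.0)
        vals = rr.daily.to_numpy()
        assert vals[5] == pytest.approx(1.0, rel=0.05)
        assert vals[-5] == pytest.approx(2.0, rel=0.05)
        diffs = np.diff(rr.daily.to_numpy())
        assert (diffs >= -1e-9).all()  # monotone transition for a step change

    def test_single_window_gives_constant_series(self):
        night = _night_frame(8, r_ref=2.0, e0=250.0, noise_sd=0.0, seed=7)
        rr = estimate_rref_moving(night, e0=250.0)
        assert np.allclose(rr.daily.to_numpy(), rr.daily.iloc[0])

    def test_lookup_covers_series_edges(self):
        night = _night_frame(40, r_ref=2.0, e0=250.0, noise_sd=0.0, seed=8)
        rr = estimate_rref_moving(night, e0=250.0)
        vals = rr.at(night.index)
        assert np.isfinite(vals).all()


class TestConfidenceBand:
    def _fit(self, noise_sd=0.1, n=400, seed=9):
        # additive noise: the band's own error model
        rng = np.random.default_rng(seed)
        ta = rng.uniform(-5, 25, n)
        er = lloyd_taylor(ta, 2.0, 300.0)
        return fit_trf(ta, er + rng.normal(0, noise_sd, n))

    def test_zero_errors_collapse_band(self):
        p = TRFParams(r_ref=2.0, e0=300.0, cov=np.zeros((2, 2)), n_fit=100)
        lo, hi = trf_confidence_band(p, np.array([0.0, 10.0, 20.0]))
        assert np.allclose(lo, hi)
        assert np.allclose(lo, p.predict(np.array([0.0, 10.0, 20.0])))

    def test_wider_level_contains_narrower(self):
        p = self._fit()
        ta = np.linspace(-5, 25, 30)
        lo95, hi95 = trf_confidence_band(p, ta, level=0.95)
        lo99, hi99 = trf_confidence_band(p, ta, level=0.99)
        assert (lo99 < lo95).all() and (hi99 > hi95).all()

    def test_missing_errors_raise(self):
        with pytest.raises(ValueError):
            trf_confidence_band(TRFParams(2.0, 300.0), np.array([5.0]))

    def test_pointwise_coverage_of_noiseless_truth(self):
        # pointwise coverage of the true curve near the nominal 95% rate
        covered = []
        ta_grid = np.linspace(-5, 25, 50)
        truth = lloyd_taylor(ta_grid, 2.0, 300.0)
        for seed in range(40):
            p = self._fit(noise_sd=0.2, n=150, seed=100 + seed)
            lo, hi = trf_confidence_band(p, ta_grid, level=0.95)
            covered.append(((truth >= lo) & (truth <= hi)).mean())
        assert 0.88 <= np.mean(covered) <= 1.0
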