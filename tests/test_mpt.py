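import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mptflux import (
    InsufficientDataError,
    MPTConfig,
    MPTResult,
    inner_scan,
    mean_difference_test,
    mpt_thresholds,
    three_sigma_filter,
    three_sigma_mask,
)
from mptflux.mpt import SCAN_LOWER, SCAN_NONE, SCAN_UPPER, scan_alpha
from .conftest import night_records


class TestThreeSigma:
    def test_gross_outlier_removed(self):
        values = np.array([1.0] * 24 + [100.0])
        assert len(three_sigma_filter(values)) == 24

    def test_moderate_deviation_retained(self):
        values = np.array([0.0, 0.0, 0.0, 10.0])
        assert len(three_sigma_filter(values)) == 4

    def test_zero_spread_retains_all(self):
        values = np.full(10, 3.3)
        assert three_sigma_mask(values).all()


class TestMeanDifferenceTest:
    def test_identical_samples_not_significant(self):
        x = np.arange(10.0)
        sig, p = mean_difference_test(x, x, alpha=0.1)
        assert not sig and p > 0.9

    def test_separated_means_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 30)
        b = rng.normal(0.2, 0.1, 30)
        sig, p = mean_difference_test(a, b, alpha=0.1)
        assert sig and p < 1e-6

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.3, 2, 50)
        _, p = mean_difference_test(a, b, alpha=0.05)
        assert p == pytest.approx(stats.ttest_ind(a, b, equal_var=False).pvalue)

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            ref = rng.normal(0, 1, 200)
            moving = np.concatenate([ref[:25]])  # subset of the reference
            rng.shuffle(ref)
            sig, _ = mean_difference_test(moving, ref, alpha=0.1)
            hits += int(sig)
        assert 0.05 <= hits / reps <= 0.16


def brute_force_scan(ustar, norm, config):
    """Independent oracle: test every moving sample, report the first hit."""
    n = config.n_moving
    N = len(norm)
    n_samples = N - n + 1
    alpha = scan_alpha(config, n_samples)
    ref = norm
    first_checked = True
    for start in range(N - n, -1, -1):
        sample = norm[start : start + n]
        diff = abs(sample.mean() - ref.mean())
        tie = diff <= 1e-6 * max(1.0, abs(sample.mean()), abs(ref.mean()))
        p = stats.ttest_ind(sample, ref, equal_var=False).pvalue
        if not tie and p < alpha:
            kind = SCAN_UPPER if first_checked else SCAN_LOWER
            return kind, float(np.median(ustar[start : start + n]))
        first_checked = False
    return SCAN_NONE, None


class TestInnerScan:
    def _fixture(self, seed, n=400, threshold=None, suppression=0.3, anomaly=False):
        # u* distribution matches the generator's nighttime regime
        rng = np.random.default_rng(seed)
        ustar = np.sort(rng.lognormal(np.log(0.45), 0.35, n))
        norm = rng.normal(1.0, 0.2, n)
        if threshold is not None:
            norm[ustar < threshold] *= suppression
        if anomaly:
            norm[-25:] *= 3.0
        return ustar, norm

    def test_agrees_with_brute_force_oracle(self):
        config = MPTConfig()
        rng = np.random.default_rng(10)
        for rep in range(30):
            style = rep % 3
            ustar, norm = self._fixture(
                seed=1000 + rep,
                n=int(rng.integers(200, 500)),
                threshold=0.3 if style == 1 else None,
                anomaly=style == 2,
            )
            outcome = inner_scan(ustar, norm, config)
            kind, candidate = brute_force_scan(ustar, norm, config)
            assert outcome.kind == kind
            if candidate is not None:
                assert outcome.candidate == pytest.approx(candidate)

    def test_flux_independent_of_ustar_is_clean(self):
        ustar, norm = self._fixture(seed=5, n=600)
        assert inner_scan(ustar, norm, MPTConfig()).kind == SCAN_NONE

    def test_low_ustar_suppression_triggers_lower(self):
        ustar, norm = self._fixture(seed=6, n=600, threshold=0.25)
        outcome = inner_scan(ustar, norm, MPTConfig())
        assert outcome.kind == SCAN_LOWER
        assert 0.20 <= outcome.candidate <= 0.30

    def test_high_ustar_anomaly_triggers_upper(self):
        ustar, norm = self._fixture(seed=7, n=400, anomaly=True)
        outcome = inner_scan(ustar, norm, MPTConfig())
        assert outcome.kind == SCAN_UPPER

    def test_vanishing_alpha_never_triggers_on_noise(self):
        config = MPTConfig(alpha_mpt=1e-12)
        for seed in range(5):
            ustar, norm = self._fixture(seed=seed, n=300)
            assert inner_scan(ustar, norm, config).kind == SCAN_NONE

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            inner_scan(np.arange(10.0), np.ones(10), MPTConfig())


class TestMPTThresholds:
    def test_no_dependence_converges_immediately(self, clean_series):
        series, _ = clean_series
        result = mpt_thresholds(night_records(series))
        assert result.converged
        assert result.ustar_low == 0.0
        assert result.ustar_high == 9999.0
        assert result.outer_iterations == 1

    def test_threshold_recovery(self, threshold_series):
        series, _ = threshold_series
        result = mpt_thresholds(night_records(series))
        assert result.converged
        assert result.ustar_low == pytest.approx(0.25, abs=0.05)
        assert result.ustar_high == 9999.0
        assert result.trf is not None and result.trf.converged

    def test_high_anomaly_sets_upper_threshold(self, scenarios):
        from mptflux.synthetic import generate

        series, truth = generate(scenarios["high_ustar_anomaly"], seed=4)
        night = night_records(series)
        result = mpt_thresholds(night)
        assert result.ustar_high < 9999.0
        # the upper threshold (median u* of the triggering top sample) sits
        # inside the anomalous u* range
        anomalous_ustar = series.data.loc[truth["anomalous"].to_numpy(), "ustar"]
        assert anomalous_ustar.min() <= result.ustar_high <= anomalous_ustar.max()
        # retained records are overwhelmingly non-anomalous
        kept = result.keep(night["ustar"].to_numpy())
        anom_night = truth.loc[night.index, "anomalous"].to_numpy()
        assert anom_night[kept].mean() < 0.05

    def test_row_order_invariance(self, threshold_series):
        series, _ = threshold_series
        night = night_records(series)
        shuffled = night.sample(frac=1.0, random_state=0)
        a = mpt_thresholds(night)
        b = mpt_thresholds(shuffled.sort_index())
        assert (a.ustar_low, a.ustar_high) == (b.ustar_low, b.ustar_high)

    def test_thresholds_ordered_and_inward(self, threshold_series):
        series, _ = threshold_series
        result = mpt_thresholds(night_records(series))
        assert 0.0 <= result.ustar_low < result.ustar_high

    def test_min_points_enforced(self):
        idx = pd.date_range("2009-01-01 00:30", periods=50, freq="30min")
        night = pd.DataFrame(
            {"nee": 0.2, "ta": 5.0, "ustar": 0.3}, index=idx
        )
        with pytest.raises(InsufficientDataError):
            mpt_thresholds(night)

    def test_literal_per_sample_rule_is_available(self, clean_series):
        # the raw p < alpha variant triggers on null data almost surely;
        # it exists as an opt-in and must stay functional
        series, _ = clean_series
        config = MPTConfig(scan_family_wise=False, max_outer_iterations=5)
        result = mpt_thresholds(night_records(series), config)
        assert result.outer_iterations >= 1
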