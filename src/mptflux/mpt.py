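"""The moving point test (MPT) for friction-velocity thresholds.

Nighttime CO2 fluxes measured under weak turbulence underestimate ecosystem
respiration; the MPT finds the intermediate u* range inside which the
normalized nighttime flux is independent of u*.  The procedure:

1.  Initialize the thresholds to (u*L, u*H) = (0, 9999).
2.  Fit the Lloyd-Taylor TRF to the records between the current thresholds
    and normalize every flux by the TRF prediction at its temperature.
3.  Drop 3-sigma outliers of the normalized flux (single pass) and sort the
    remaining in-threshold records by ascending u* (ties keep time order).
4.  Scan moving samples of ``n_moving`` consecutive-u* points from the
    highest-u* end downward, one point per step, Welch-testing each sample
    mean against the mean of the whole in-threshold reference sample.
    At the first sample that differs significantly: if it is the very first
    (highest-u*) sample, its median u* becomes the new upper threshold;
    otherwise its median u* becomes the new lower threshold.
5.  Any update returns to step 2; a full scan with no update terminates the
    outer loop (converged).

Significance level: ``alpha_mpt`` (default 0.1) is interpreted as the
family-wise level of one whole scan.  A scan performs hundreds of strongly
overlapping tests; comparing each raw p-value against ``alpha_mpt`` would
flag a threshold on virtually every dataset, including u*-independent ones.
Each moving-sample test is therefore compared against a Bonferroni-adjusted
per-comparison level ``alpha_mpt / n_samples``.  Set
``MPTConfig.scan_family_wise = False`` for the literal per-sample rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .flux_io import NO_UPPER_SENTINEL
from . import trf as _trf

SCAN_NONE = "none"
SCAN_LOWER = "lower"
SCAN_UPPER = "upper"

# relative mean differences below this are numerical ties, not signal
# (guards against fit-residual jitter on noiseless or near-noiseless data)
_NUMERICAL_TIE = 1e-6


@dataclass
class MPTConfig:
    """Tuning constants for the moving point test."""

    n_moving: int = 25
    alpha_mpt: float = 0.1
    max_outer_iterations: int = 50
    min_points: int = 100
    scan_family_wise: bool = True

    def __post_init__(self) -> None:
        if self.n_moving < 5:
            raise ValueError("n_moving must be at least 5")
        if not 0.0 < self.alpha_mpt < 1.0:
            raise ValueError("alpha_mpt must be in (0, 1)")


@dataclass
class ScanOutcome:
    """Result of one inner scan over the sorted in-threshold records."""

    kind: str  # none | lower | upper
    candidate: float | None = None  # median u* of the triggering sample
    index: int | None = None  # scan position (0 = highest-u* sample)
    p: float | None = None


@dataclass
class MPTResult:
    """Detected u* thresholds for one data subset.

    ``ustar_low = 0`` means no lower threshold was found and
    ``ustar_high = 9999`` (sentinel) means no upper threshold was found.
    """

    ustar_low: float = 0.0
    ustar_high: float = NO_UPPER_SENTINEL
    outer_iterations: int = 0
    converged: bool = False
    n_used: int = 0
    trf: _trf.TRFParams | None = None
    message: str = ""

    def keep(self, ustar) -> np.ndarray:
        """Boolean mask of u* values strictly inside the thresholds."""
        ustar = np.asarray(ustar, dtype=float)
        return (ustar > self.ustar_low) & (ustar < self.ustar_high)


def three_sigma_filter(values) -> np.ndarray:
    """Values retained by a single-pass 3-sigma outlier rule."""
    values = np.asarray(values, dtype=float)
    return values[three_sigma_mask(values)]


def three_sigma_mask(values) -> np.ndarray:
    """Boolean mask of values within 3 sample standard deviations of the mean.

    With zero spread every value is retained.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.ones(len(values), dtype=bool)
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.ones(len(values), dtype=bool)
    return np.abs(values - values.mean()) <= 3.0 * sd


def mean_difference_test(moving, reference, alpha: float) -> tuple[bool, float]:
    """Welch two-sample t-test of mean equality.

    Returns ``(significant, p)`` with ``significant`` meaning ``p < alpha``.
    Two degenerate zero-variance samples with equal means give p = 1.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(moving) < 2 or len(reference) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    m1, m2 = moving.mean(), reference.mean()
    if abs(m1 - m2) <= _NUMERICAL_TIE * max(1.0, abs(m1), abs(m2)):
        return False, 1.0  # numerically identical means (e.g. noiseless data)
    if moving.var(ddof=1) == 0 and reference.var(ddof=1) == 0:
        p = 0.0
    else:
        p = float(stats.ttest_ind(moving, reference, equal_var=False).pvalue)
    return p < alpha, p


def _welch_p(m_mean, m_var, n, ref_mean, ref_var, n_ref):
    """Vectorized Welch p-values of moving samples against one reference."""
    v1 = m_var / n
    v2 = ref_var / n_ref
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m_mean - ref_mean) / np.sqrt(denom)
        df = denom**2 / (v1**2 / (n - 1) + v2**2 / (n_ref - 1))
    p = np.where(
        denom > 0,
        2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1.0)),
        np.where(m_mean == ref_mean, 1.0, 0.0),
    )
    tie = np.abs(m_mean - ref_mean) <= _NUMERICAL_TIE * np.maximum(
        1.0, np.maximum(np.abs(m_mean), np.abs(ref_mean))
    )
    return np.where(tie, 1.0, p)


def scan_alpha(config: MPTConfig, n_samples: int) -> float:
    """Per-comparison significance level for a scan of ``n_samples`` tests."""
    if config.scan_family_wise and n_samples > 0:
        return config.alpha_mpt / n_samples
    return config.alpha_mpt


def inner_scan(ustar, norm, config: MPTConfig | None = None) -> ScanOutcome:
    """One scan of moving samples from the highest u* downward.

    ``ustar`` and ``norm`` are the friction velocities and normalized fluxes
    of the in-threshold, outlier-filtered records, sorted by ascending u*
    (ties in time order).  Returns the first significantly differing moving
    sample as a threshold candidate, or ``kind="none"`` for a clean scan.
    """
    config = config or MPTConfig()
    ustar = np.asarray(ustar, dtype=float)
    norm = np.asarray(norm, dtype=float)
    n = config.n_moving
    N = len(norm)
    if N < n:
        raise InsufficientDataError(f"{N} records < moving sample size {n}")

    windows = np.lib.stride_tricks.sliding_window_view(norm, n)
    m_mean = windows.mean(axis=1)
    m_var = windows.var(axis=1, ddof=1)
    ref_mean = norm.mean()
    ref_var = norm.var(ddof=1)
    p = _welch_p(m_mean, m_var, n, ref_mean, ref_var, N)

    n_samples = N - n + 1
    alpha = scan_alpha(config, n_samples)
    # scan order: start positions from the top of the u* range downward
    starts = np.arange(n_samples - 1, -1, -1)
    sig = p[starts] < alpha
    if not sig.any():
        return ScanOutcome(kind=SCAN_NONE)
    first = int(np.argmax(sig))
    start = int(starts[first])
    candidate = float(np.median(ustar[start : start + n]))
    kind = SCAN_UPPER if first == 0 else SCAN_LOWER
    return ScanOutcome(kind=kind, candidate=candidate, index=first, p=float(p[start]))


def mpt_thresholds(night: pd.DataFrame, config: MPTConfig | None = None) -> MPTResult:
    """Run the full MPT outer loop on nighttime records.

    ``night`` needs ``nee``, ``ta`` and ``ustar`` columns (efflux positive);
    rows with a missing value in any of the three are ignored.  Thresholds
    only move inward across outer iterations.
    """
    config = config or MPTConfig()
    cols = night[["nee", "ta", "ustar"]].to_numpy(float)
    ok = np.isfinite(cols).all(axis=1)
    nee, ta, ustar = cols[ok, 0], cols[ok, 1], cols[ok, 2]
    if len(nee) < config.min_points:
        raise InsufficientDataError(
            f"{len(nee)} usable nighttime records < min_points {config.min_points}"
        )

    lo, hi = 0.0, NO_UPPER_SENTINEL
    result = MPTResult()
    fit = None
    for iteration in range(1, config.max_outer_iterations + 1):
        sel = (ustar > lo) & (ustar < hi)
        if sel.sum() < max(config.n_moving, 10):
            result.message = "too few in-threshold records to continue"
            break
        try:
            fit = _trf.fit_trf(ta[sel], nee[sel])
        except InsufficientDataError as exc:
            result.message = f"TRF fit impossible: {exc}"
            break
        if not fit.converged:
            result.message = f"TRF fit did not converge: {fit.message}"
            break

        er = fit.predict(ta[sel])
        normv = nee[sel] / er
        keep = three_sigma_mask(normv)
        u_sel = ustar[sel][keep]
        n_sel = normv[keep]
        order = np.argsort(u_sel, kind="stable")  # ties stay in time order
        try:
            outcome = inner_scan(u_sel[order], n_sel[order], config)
        except InsufficientDataError as exc:
            result.message = str(exc)
            break

        result.outer_iterations = iteration
        if outcome.kind == SCAN_NONE:
            result.converged = True
            break
        if outcome.kind == SCAN_LOWER:
            if outcome.candidate <= lo:
                result.message = "lower-threshold candidate made no progress"
                break
            lo = float(outcome.candidate)
        else:
            if outcome.candidate >= hi:
                result.message = "upper-threshold candidate made no progress"
                break
            hi = float(outcome.candidate)

    sel = (ustar > lo) & (ustar < hi)
    result.ustar_low = lo
    result.ustar_high = hi
    result.n_used = int(sel.sum())
    # final TRF on the retained records, for reporting and normalization
    if sel.sum() >= 10 and np.ptp(ta[sel]) >= 2.0:
        final = _trf.fit_trf(ta[sel], nee[sel])
        result.trf = final if final.converged else fit
    else:
        result.trf = fit
    return result
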