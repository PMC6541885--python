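# Methods

This note documents the models, statistical procedures and design choices
behind `mptflux`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and what the synthetic tests do and do
not demonstrate.

## Data model and conventions

Half-hourly records with timestamps labelling the **end** of each averaging
interval, local standard time, no DST.  NEE is in mg CO₂ m⁻² s⁻¹ with
efflux positive (negative = uptake) and is assumed to already contain the
storage term; a separately stored storage column can be mapped and is summed
into NEE on read.  Missing values are −9999 on disk and NaN in memory; grid
gaps become explicit `qc = missing` rows.  "Night" is incoming shortwave
below 10 W m⁻² (strictly; configurable) — a radiation cutoff needs no site
coordinates or solar geometry.  A record ending exactly at midnight belongs
to the day it measured, which keeps quarter boundaries (DOY 1–90, 91–181,
182–273, 274–365/366) unambiguous.

If u* is absent, it is computed from the momentum covariances as
u* = (u'w'² + v'w'²)^¼.

## Lloyd–Taylor respiration model

ER(Ta) = R_ref · exp(E0 · (1/(T_ref − T0) − 1/(Ta − T0))), T_ref = 10 °C,
T0 = −46.02 °C.  E0 carries units of °C, as the exponent's
inverse-temperature differences require.  Fits use trust-region nonlinear
least squares (`scipy.optimize.curve_fit`, method `trf`) with initial guess
(mean flux, 309 °C) and bounds R_ref ∈ (0, 100], E0 ∈ [10, 600].
Non-convergence is returned as a flagged result, never an exception, so a
threshold-detection loop can abort gracefully.

* **Site-year E0** ("short-term sensitivity" procedure): 15-day windows
  stepped 5 days over the retained nighttime data; a window is accepted with
  ≥ 6 pairs, Ta range ≥ 5 °C and E0 ∈ [30, 450]; the site-year value is the
  mean of the three accepted estimates with the smallest relative standard
  error.  With no accepted window the literature default E0 = 309 °C is
  used and flagged — never silently.
* **R_ref**: one-parameter fits (E0 fixed) over 30-day windows stepped
  5 days, tracking soil-moisture/phenology variation the closed form
  ignores; daily values interpolate linearly between window centers, and
  windows with < 6 pairs inherit the nearest valid window's value.
* **Bands**: the confidence band for the mean curve propagates the
  parameter covariance through the closed form (delta method) with a
  Student-t quantile at n − k degrees of freedom — deterministic and cheap.
  The *prediction* band, used by the underestimation filter, adds an
  observation-scatter term that scales with the predicted flux, matching
  the multiplicative error character of nighttime EC data; a pooled
  absolute variance would be far too wide at cold temperatures and too
  narrow at warm ones.

## The moving point test

Per data subset (a three-month period, one time window): initialize
(u*_L, u*_H) = (0, 9999); then loop

1. fit the TRF to records with u*_L < u* < u*_H;
2. normalize fluxes by the TRF prediction at each record's Ta;
3. drop |x − mean| > 3 σ outliers (single pass) and sort by ascending u*
   (ties keep time order, for determinism);
4. slide moving samples of n = 25 consecutive-u* points from the highest
   u* downward one record per step, Welch-testing each sample mean against
   the mean of the whole in-threshold reference sample (overlap allowed);
5. at the first significantly differing sample: if it is the very first
   (highest-u*) sample, its median u* becomes u*_H, otherwise u*_L; any
   update restarts from step 1;
6. a full clean scan terminates (converged); thresholds only move inward;
   a 50-iteration cap guards against non-convergence.

**Why the significance level is scan-wise.**  One scan performs hundreds of
strongly overlapping Welch tests.  If each raw p-value were compared with
α_MPT = 0.1, the probability of at least one false trigger on
u*-independent data is essentially 1 (measured: every one of 200 null
scans triggered somewhere), so the procedure would "find" thresholds in
any dataset and the outer loop would ratchet them inward without limit.
α_MPT is therefore interpreted as the family-wise level of the whole scan:
each sample's p-value is compared against α_MPT / n_samples (Bonferroni).
This preserves the published constants (α_MPT = 0.1, n = 25) while giving
the procedure its intended operating characteristic: clean data yields
(0, 9999) in ≈ 90 % of runs, and a genuine suppression onset — whose
t-statistics are enormous — is still detected.  `MPTConfig
(scan_family_wise=False)` restores the literal per-sample rule for
comparison.

Numerical floor: mean differences below 10⁻⁶ (relative to the flux scale)
are treated as ties.  On noiseless data the normalized fluxes are 1 ± fit
jitter, and t-statistics computed on that jitter would otherwise be
meaningless rejections.

The upper-threshold branch (first sample differs) catches *moderate* flux
elevation at the top of the u* range.  A gross, many-sigma anomaly is
removed by the 3σ outlier rule before the scan ever sees it — the two
mechanisms are complementary, and the synthetic anomaly scenario uses a
×1.5 elevation for that reason.

## Two-time-window modification and the drainage test

The median diurnal cycle of observed NEE (per half-hour slot, ≥ 7 days)
peaks near sunset, before drainage develops.  The peak is searched in
15:00–22:00 local (configurable; ties → earliest slot; a peak on the search
boundary is flagged).  Window 1 spans [peak − 1 h, peak + 2 h] — drainage
develops after the peak, so the window extends further after than before;
window 2 is the remainder of the night, wrapping midnight.  The MPT runs
independently per window (a window whose MPT fails falls back to the fixed
0.3 m s⁻¹ threshold, flagged).

Midnight drainage is then declared when the mean normalized, u*-filtered
flux of window 2 is significantly below window 1's (Welch test,
α_drain = 0.05, one-sided decision: a *higher* window-2 mean is not
drainage).  Both windows are normalized by the same TRF: R_ref fitted on
window-1 retained records — the less-contaminated window — with E0 held at
the site-year estimate.  E0 cannot be identified from a ~3-hour window's
narrow temperature range; fitting both parameters there misextrapolates to
window 2's colder late-night temperatures and produced spurious drainage
calls in early testing, which is why the temperature sensitivity is pinned.
Fewer than 10 u*-filtered records in either window makes the test
undetermined, treated as negligible with a flag.

If drainage is significant every window-2 night record is rejected
(reason `second_window_drainage`) and only window 1 feeds the respiration
fit; otherwise each window is filtered by its own thresholds (reasons
`low_ustar`, `high_ustar`).

## Gap-filling, partitioning, budgets

Rejected/missing night fluxes become TRF predictions at the record's Ta
(interpolated across gaps up to 3 h; records still lacking Ta stay missing
and are counted).  Daytime ER is the TRF evaluated at daytime Ta — the
standard nighttime-to-daytime extrapolation; daytime NEE is never filtered
(the daytime boundary layer is well mixed) and daytime gaps are not filled
here (marginal-distribution sampling is out of scope; budgets therefore
require gap-free daytime input, which the generator provides).  GPP = ER −
NEE with nighttime GPP forced to zero — observed night flux *is* the ER
observation, so any residual stays in NEE rather than leaking into GPP.
Budgets integrate half-hours (× 1800 s) and convert mg CO₂ to g C with
12.011/44.009.  NEE = ER − GPP holds record-wise, hence exactly in the
sums.

## Baselines

* **FVF**: reject night records with u* < 0.3 m s⁻¹ (site baseline value);
  daytime untouched.
* **LRC**: daytime ER as the zero-light intercept R_LRCd of a
  Michaelis–Menten light response NEE = R_LRCd − αQ·A_max/(αQ + A_max),
  fitted per centered 30-day window; daily values paired with the window's
  mean daytime Ta feed the TRF.  Note the intercept absorbs the diel
  covariance of respiration and radiation (warm afternoons are bright), a
  known bias of the method that the comparison inherits deliberately.
* **VGF**: daily R_max = the sunset peak of the 30-day median diurnal
  cycle, paired with the median Ta of the peak slot (the temperature
  pairing is not prescribed anywhere; the slot median is the consistent
  choice).
* LRC and VGF additionally reject observed night fluxes below the lower
  95 % prediction bound of the fitted ER model (underestimation only).

## Synthetic generator

The generator emulates the phenomena the method targets, not a physical
boundary layer:

* diel (optionally seasonal) air temperature, default 12 ± 5 °C peaking at
  14:00 — night temperatures span ~7 °C, enough for the E0 machinery;
* Lloyd–Taylor respiration truth (R_ref = 0.2 mg CO₂ m⁻² s⁻¹, E0 = 309 °C)
  and Michaelis–Menten daytime uptake (α = 0.002, A_max = 1.5) under a
  solar-shaped radiation curve (800 W m⁻² peak, daylight 06–18 h);
* lognormal u* (night median 0.45 m s⁻¹, log-sd 0.35; day median 0.55).
  This is a strong-turbulence regime: ~5 % of night records fall below the
  true 0.25 m s⁻¹ threshold and ~12 % below the 0.3 m s⁻¹ baseline —
  the plateau-dominated geometry the moving point test presumes, while
  still populating both u* strata well beyond the moving-sample size;
* measured night flux × suppression factor (0.3) below the threshold;
  drainage as a clock window from 2 h after the evening flux peak to
  sunrise, suppressing measured fluxes (× 0.3) regardless of u* — the
  method only sees drainage's statistical signature, so no physical
  drainage model is attempted;
* mean-one lognormal multiplicative noise (sd 20 %) plus small additive
  noise (0.01), night-only missingness (10 %).

Truth frames carry exact ER/GPP/NEE and the suppression/window flags, so
recovery is scored against known values.

**What passing tests show — and don't.**  The synthetic regime has a sharp
suppression step, stationary respiration parameters, and u* independent of
temperature.  Real sites have gradual u* responses, correlated
meteorology, storage-flux errors and instrument artifacts; threshold
recovery within ±0.05 m s⁻¹ here does not promise that accuracy in the
field.  Sites where most of the night sits *below* the threshold (weak
turbulence regimes) blend the reference sample and degrade the scan's
localization — a real limitation of the reference-sample formulation, not
of this implementation.  Likewise, when drainage rejects all of window 2,
the respiration fit rests on a ~3-hour evening window: E0 usually falls
back to the default and R_ref extrapolates over the whole night, which is
exactly the information loss a real tower would face.

## Numerical and reproducibility choices

Everything downstream of a seed is deterministic: stable sorts break u*
ties by time, scans are vectorized but bit-reproducible, and rerunning any
command with the same config/seed reproduces byte-identical outputs.
Degenerate inputs (zero variance, noiseless data, empty slots, windows with
too few records) have explicit conventions rather than incidental
behavior: zero spread retains all values in the 3σ rule, equal-mean
zero-variance samples give p = 1, unobserved diurnal slots are absent (not
zero), and unfillable records are counted and reported.

Problem sizes in the test-suite simulations (50 seeds of 90-day series for
threshold/drainage rates; 50 one-year series for the budget comparison)
were chosen as the smallest sets at which the binomial rate criteria are
meaningful.
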