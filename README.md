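# mptflux

Nighttime CO₂ flux filtering and correction for eddy-covariance towers on
hilly and complex terrain.

## The problem

Eddy-covariance towers measure the net ecosystem exchange of CO₂
(NEE = eddy flux + storage flux).  At night, two things corrupt the
measurement on sloping terrain:

1. **Weak turbulence.**  When the friction velocity u* is low, the measured
   flux underestimates ecosystem respiration (ER).  The classical remedy is
   friction-velocity filtering (FVF): discard night records below a u*
   threshold.
2. **Cold-air drainage.**  Downslope flows carry respired CO₂ away below
   the sensor, so measured fluxes sit near zero *even when u* is high*.  A
   u* filter cannot catch this; the van Gorsel approach instead keeps only
   the flux peak near sunset, before drainage develops.

`mptflux` implements a hybrid of the two: the **modified moving point test
(MPT)**.  Per three-month period it

1. locates the evening peak of the median diurnal flux cycle (≈ sunset) and
   splits the night into **window 1** (1 h before to 2 h after the peak) and
   **window 2** (the rest of the night);
2. runs the moving point test independently in each window to find the
   lower/upper u* thresholds (u*_L, u*_H) inside which the normalized
   nighttime flux is independent of u*;
3. tests the significance of **midnight drainage** by comparing the mean
   normalized, u*-filtered fluxes of the two windows (same temperature
   response function for both);
4. if drainage is significant, rejects all window-2 night records;
   otherwise filters each window by its own thresholds.

Rejected and missing night fluxes are replaced by the Lloyd–Taylor
temperature response function (TRF)

    ER(Ta) = R_ref · exp( E0 · ( 1/(T_ref − T0) − 1/(Ta − T0) ) ),

with T_ref = 10 °C, T0 = −46.02 °C, a constant site-year E0 estimated from
short-term (15-day) windows, and R_ref from a 30-day moving window shifted
every 5 days.  Daytime ER is extrapolated from the nighttime relationship
and NEE is partitioned as GPP = ER − NEE.  The traditional corrections
(fixed-threshold FVF, light-response-curve method, van Gorsel R_max method)
are included for comparison.

In the moving point test, moving samples of n = 25 consecutive-u* points
are Welch-tested against the in-threshold reference sample while sliding
down from the highest u*; the first significantly differing sample updates
a threshold (median u* of that sample) and the outer loop refits the TRF
until a scan is clean.  α_MPT = 0.1 is applied as the family-wise level of
a whole scan (see `docs/methods.md`).

## Worked example

Generate a synthetic 90-day series with a known u* threshold (0.25 m s⁻¹,
suppression ×0.3) plus post-sunset drainage, then detect thresholds:

```
$ mptflux simulate --scenario threshold_plus_drainage --seed 7 --out demo
wrote demo/series.csv and demo/truth.csv

$ mptflux thresholds demo/series.csv --out demo_thr
site  year  doy ustar_low_w1 ustar_high_w1 ustar_low_w2 ustar_high_w2    drainage
site  2009 1-90        0.000          9999        0.249          9999 significant
```

Window 2's lower u* threshold (0.249 m s⁻¹) recovers the generator's true
0.25 m s⁻¹; `9999` is the sentinel for "no upper threshold found"; the
drainage column reports that window-2 fluxes are significantly below
window-1 fluxes after u* filtering, so the whole second window will be
rejected and gap-filled.  (In the short near-peak window 1 only a handful
of records fall below the true threshold, so no threshold is resolvable
there — its `0.000` means "no lower threshold found".)

`mptflux correct demo/series.csv --out demo_corr` then runs the full
pipeline (filter → TRF fit → gap-fill → partition) and writes the
partitioned half-hourly series with reason codes; on a full-year input it
also writes the annual NEE/GPP/ER budget in g C m⁻² yr⁻¹ and, with
`--compare`, a method-comparison table against FVF, LRC and VGF.

The same machinery is available as a library:

```python
from mptflux import correct, run_modified_mpt, read_halfhourly_csv
series = read_halfhourly_csv("demo/series.csv")
result = run_modified_mpt(series)        # thresholds + drainage + mask
corrected = correct(series, method="mpt")  # full pipeline
```

## Layout

- `flux_io` — data model, CSV dialect (−9999 missing), night flagging,
  quarter segmentation, report writer
- `trf` — Lloyd–Taylor evaluation/fitting, site-year E0, moving R_ref,
  confidence/prediction bands
- `mpt` — 3σ outlier rule, Welch scan, outer threshold loop
- `drainage` — diurnal cycle, sunset-peak window split, drainage test,
  modified-MPT orchestration
- `baselines` — FVF, light-response curve, van Gorsel R_max, CI filter
- `partition_ops` — gap-filling, daytime ER, GPP/ER partitioning, budgets
- `synthetic` — half-hourly generator with known truth and scenario library
- `pipeline`, `cli` — end-to-end runs and the `mptflux` command
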