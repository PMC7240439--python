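# Methods

## Measurement model and analysis scale

The package treats a wearable reading as a multiplicatively noisy version
of the criterion value. Both measures are transformed to `100·ln(x)`
before analysis; on that scale multiplicative error is additive, and an
SD of *s* corresponds to a CV of `100·(exp(s/100) − 1)` ≈ *s* percent for
small *s* (within 3% of *s* up to *s* = 5). The transform requires
strictly positive inputs, which heart rate (bpm) and per-bout energy
expenditure (kcal) satisfy.

## Per-cell statistics

For each device × condition cell with n complete pairs (minimum 4, so
every confidence-limit computation below is defined):

- **Regression TEE.** The criterion (log scale) is regressed on the
  device reading (log scale) by ordinary least squares. The regression
  runs in this direction so that the typical error of the estimate (TEE)
  — the residual SD with n−2 degrees of freedom — is the expected error
  when inferring the true value from the wearable. The TEE is
  back-transformed to CV%.
- **sTEE.** `sqrt(1/r² − 1)` computed from the log-scale correlation.
  This equals TEE divided by the SD of the regression-predicted criterion
  values, and it reproduces the r ↔ sTEE pairings of published validity
  tables (r = 0.85 ↔ sTEE = 0.62), which plain TEE/SD(criterion) does
  not. It is undefined at r = 0; the summary layer then reports NaN with
  an explicit flag rather than raising.
- **Standardized mean bias.** Mean log difference divided by the
  between-subject criterion log-SD.
- **Pearson r** is reported on the *raw* scale (the convention that
  reconciles most published r/sTEE pairs), while the sTEE uses the
  log-scale correlation. The two are typically close; they are kept
  distinct deliberately.

### Confidence limits (90% by default)

The distributional choices are the standard ones for normal-theory
regression; the confidence level is configurable via `level`:

| statistic | interval |
| --- | --- |
| TEE / CV | chi-square on the residual variance, n−2 df: `tee·sqrt(df/χ²_q)` at the (1±level)/2 quantiles, then back-transformed |
| Pearson r | Fisher z, normal with SE `1/sqrt(n−3)`; collapses to r at \|r\| = 1 |
| mean bias | Student t, n−1 df, on the mean difference, standardized afterwards |
| sTEE | monotone image of the Fisher limits of the log-scale r; if that interval reaches 0 the upper sTEE limit is unbounded (+inf, flagged) |

Empirical coverage of the chi-square CV limits is verified by simulation
(2000 replicates at n = 25, 90% ± 3%).

## Rating scales and derived quantities

- sTEE bins (half the modified-Cohen thresholds): [0, 0.1) trivial,
  [0.1, 0.3) small, [0.3, 0.6) moderate, [0.6, 1.0) large, [1.0, 2.0]
  very large, above 2.0 extremely large. The closed edge at 2.0 follows
  the scale's "1.0–2.0 / >2.0" phrasing.
- Pearson bins: [0.45, 0.70) very poor, [0.70, 0.85) poor, [0.85, 0.95)
  good, [0.95, 0.995) very good, [0.995, 1] excellent; below 0.45 no
  rating is assigned (rendered "-"). Classification always operates on
  unrounded values, so r = 0.99 rates "very good" even though it prints
  as 0.99.
- MET level: `EE_bout · (60/bout_min) / body_mass` (kcal·kg⁻¹·h⁻¹);
  < 3 light, [3, 6) moderate, ≥ 6 vigorous. The boundary value 6 is
  assigned to vigorous.
- Absolute error: `CV/100 × criterion mean`, in original units.
  Device-level summaries average per-condition absolute errors (HR), or
  apply the mean CV to the grand criterion mean and extrapolate the bout
  to one hour (EE) — two distinct aggregations, both matching the
  published derivations.
- Average rows are unweighted means of the per-condition point
  estimates; no confidence limits are aggregated.

## Data handling

Input is long-format CSV (one row per participant × device × condition;
a column-name dialect can map external headers). Values must be finite
and positive; violations name the offending row. Missing pairs are
dropped pairwise per cell. When a `t_s` column marks time-stamped
samples, bouts are aggregated by the arithmetic mean over the retained
window, with a configurable initial-discard (default 0 s) for start
transients; aggregation is order-invariant within the window. All
numbers are stored at full precision; rounding (bias/r/sTEE to 2 dp, CV
to 1 dp) happens only at report rendering. JSON summary tables
round-trip losslessly (CSV ingestion uses round-trip float parsing).

## Synthetic cohorts and calibration

The generator emulates the validation-study design: 25 participants ×
7 five-minute conditions × 4 devices. Criterion values are drawn
normally with the published condition means/SDs, truncated at a floor of
1% of the condition mean (redraw on violation) to keep the log transform
defined; one criterion draw per participant × condition is shared across
devices, as the criterion instrument is worn once. Device readings
follow `device = exp((a + b·100·ln(criterion) + ε)/100)` with
`ε ~ N(0, σε)` — a fixed bias plus multiplicative log-normal noise,
matching the heteroscedasticity rationale for the log transform. An
additive-error variant is not needed for recovery testing and is not
modelled; neither is between-condition correlation within a participant
(the analysis treats conditions independently).

**Truth-implied statistics.** Under this model with criterion log-SD
σy (delta-method: `100·SD/mean`), the population values are
r = bσy/√(b²σy²+σε²), TEE = σyσε/√(b²σy²+σε²), sTEE = σε/(bσy), and
bias = (a + (b−1)µy)/σy. Recovery tests compare pipeline estimates to
these implied values; note the implied TEE is *smaller* than σε (the
regression exploits the correlation), so recovering the nominal error CV
itself carries a structural attenuation of a few percent at the HR
dispersion levels — the estimator is unbiased for the implied CV, which
is what the 100-seed recovery suite checks.

**Calibration choice.** The per-cell defaults are derived from the
published sTEE and standardized bias (`σε = sTEE·σy`, `a = bias·σy`,
b = 1), not from the published CV: under this model the population TEE
is bounded above by σy, and several published EE cells print CVs above
that bound (e.g. sitting CV 26.6% with SD/mean ≈ 21%), so no error SD
can reproduce them, whereas the sTEE/bias calibration is always
solvable. Simulated cohorts therefore reproduce the published bias and
sTEE structure exactly in expectation, and the CV structure only up to
the model bound.

**Known generator limitations.** The published EE SDs at 3.6/4.1 m/s
(26.7 at mean 60.5; 46.6 at mean 77.8) are so large relative to the
means that a truncated normal necessarily redraws ~1–5% of draws in
those cells; the <0.1% truncation guarantee holds for the full HR
protocol and the EE sitting cell. No physiological kinetics (HR drift,
EPOC) or motion-artifact bursts are modelled — passing recovery tests
demonstrates correctness of the statistics under the assumed error
model, not device behaviour on real data.

The AR(1) time-series generator (for bout-aggregation testing) places
stationary fluctuations with configurable relative SD (default 2%) and
lag-1 autocorrelation around each bout's pair values.

## Problem sizes used in the test and acceptance suites

Parameter-recovery runs use n = 1000 participants (100 seeds for the
bias/coverage suites); confidence-limit coverage uses 2000 replicates at
the study's n = 25; truncation-rate checks use 20k–50k draws. These
sizes put Monte-Carlo error well below the asserted tolerances while
keeping the full suite in the tens of seconds.

## Known analysis limitations

- Bland–Altman limits of agreement, mixed-effects/repeated-measures
  modelling, and inferential between-device comparisons are out of scope.
- The raw-vs-log scale convention for the reported r does not reconcile
  every published r/sTEE pair (one sprint-condition cell prints
  r = 0.53 with sTEE = 1.94 where `sqrt(1/r²−1)` gives 1.60); the
  package does not force agreement.
- How the original study time-aligned device exports to bouts is
  unknown; bout aggregation is therefore configurable rather than fixed.
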