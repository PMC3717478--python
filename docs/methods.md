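# Methods

This note documents the models, conventions and numerical choices
behind `actiflux`, and what the synthetic-data generator does and does
not emulate.

## Signal model

The simulator is a deliberately minimal generative model of a
waist-worn triaxial accelerometer (±6 g, 30 Hz; axes x = medio-lateral,
y = vertical, z = anterior–posterior):

* **Postures** (lying, sitting, standing) are a constant gravity unit
  vector plus white Gaussian noise (defaults 0.02–0.03 g).  The three
  orientations are distinct, so postures are separable by frame means.
* **Locomotion** (slow walking 1.5 Hz / 0.25 g, fast walking 2.0 Hz /
  0.45 g, running 2.8 Hz / 0.80 g) adds a gait sinusoid on the
  vertical axis and a half-amplitude, quarter-period-shifted copy on
  the anterior axis, plus noise (0.05 g).  Intensities are separable by
  vertical variance/energy.
* **Device off** is one of three fixed table orientations with 0.002 g
  noise — the near-zero variance signature that identifies non-wear.

Samples are clipped to the ±6 g device range.  Defaults keep all seven
classes separable at noise SD ≤ 0.05 g, which is what the
classification stage assumes of real reference data; the model makes
no attempt at biomechanical realism (no harmonics, no step asymmetry,
no posture transitions), so classifier accuracies obtained on it are a
*ceiling*, not an estimate of field performance.

## Frame features

Frames are non-overlapping, 2.5 s long (75 samples at 30 Hz); a
trailing partial frame is discarded.  Per axis and frame: mean,
population (1/n) variance, and spectral energy defined as the sum of
squared DFT magnitudes excluding the zero-frequency component,
normalized by the squared frame length — so a sinusoid of amplitude *a*
spanning whole cycles has energy *a*²/2, and by Parseval's identity the
energy equals the frame's mean squared deviation from its mean (the
test suite verifies this identity against direct time-domain
summation; note it makes energy numerically equal to the population
variance — the construction is kept because excluding the DC term is
what prevents gravity from dominating the feature).  Inter-axis
correlations are product-moment correlations of the within-frame
samples; an axis whose variance is at numerical rounding level for its
magnitude (var ≤ 1e-13·(1 + mean²)) is treated as constant and its
correlations are 0 by convention, which keeps device-off frames finite.

## Classifier

A multiclass SVM with RBF kernel, C = 1, kernel width γ = 1/12
(1/n_features), one-vs-one voting, on features standardized to zero
mean / unit scale with parameters frozen from the training set
(zero-variance features keep unit scale).  Training requires all seven
classes with ≥ 5 frames each.  The general model is trained on the
concatenation of all participating children's reference sets and is
used only for children without their own session.  Persistence stores
hyperparameters plus the training set and refits on load, which is
deterministic and independent of the fitting library's internals.

## Cleaning

The consolidation rule, stated precisely: an epoch interval qualifies
for merging when it starts and ends with non-wear, every embedded
activity burst (maximal run of non-non-wear epochs) lasts ≤ 5 min, the
total embedded activity is ≤ 5 min, and the interval's non-wear
content is ≥ 60 min.  All epochs in the union of qualifying intervals
become non-wear; afterwards any remaining non-wear run shorter than
60 min is re-classified as sitting (sedentary).  The rule runs once and
is idempotent.  Two readings were genuinely open: whether "1 h of
non-wear" bounds each side of a burst or the block aggregate (we use
the aggregate), and whether 5 min bounds each burst or the block total
(we enforce both).  The implementation works on wear/non-wear runs in
linear time; the test suite checks it against an exhaustive O(n²)
interval enumeration on all short label sequences.

Wake windows are half-open `[wake, bed)` by epoch start time.  A
morning diary row reports the wake time of its date and the bed time of
the previous night, so day *d*'s window pairs *d*'s wake time with the
bed time from *d+1*'s report; the last study day falls back to the
child's median bed clock-time, and a day without a diary row retains no
epochs (and is therefore invalid).  A valid day has ≥ 6 h (inclusive)
of non-non-wear epochs inside the window; days are attributed by
calendar date in local time.

## Daily measures and descriptives

Categories: lying/sitting → sedentary, standing → inactive, walking →
MVPA, running → very vigorous.  `pa_fraction` = (MVPA + very
vigorous) / wear time; `vigorous_share` = very vigorous / active time,
defined as 0 (and flagged) on zero-active days so the day still enters
models through `pa_fraction`.  Affect day scores average each factor's
three items per occasion and the occasion composites per day; an
occasion enters only when all three items are present, fewer than four
answered occasions are averaged as available (recorded in
`n_occasions_used`), and a factor with no complete occasion is missing
for that day.  The ICC is estimated from the empty two-level model
(random-intercept REML) as between-variance over total; a one-way
method-of-moments estimator (`icc_anova`) serves as the independent
cross-check, and with a single child the ICC is reported missing.

## Mixed models

Day-level model per outcome/PA pair, with `Trend` coded 0, 1, 2, … from
each child's first study day and the PA variable split into the child
mean (`pa_between`, child-constant with a fixed slope — the only
estimable reading of a between-person covariate) and the daily
deviation (`pa_within`, mean zero within child):

```
y = (γ00 + σ0i) + (γ10 + σ1i)·Trend + γ20·pa_between + (γ30 + σ3i)·pa_within + ε
```

Random intercept and trend carry a free 2×2 covariance; the random
daily-activity slope is an independent variance component.  The
sequence empty → trend_only → fixed_only → fixed_and_random is fitted
by REML; because REML likelihoods are not comparable across
fixed-effect structures, nested −2LL comparisons should use `reml=False`
refits.  Fixed effects get Wald z-tests without small-sample df
correction (users wanting Satterthwaite should refit elsewhere).
Days with missing outcome or PA are dropped listwise; at least two
children with two retained days each are required, and a design with
all-zero within-person deviations is flagged inestimable.

Numerical choices: optimization tries L-BFGS, then Powell, then CG; a
solution on a variance boundary (or with a non-finite restricted
likelihood) is re-checked with BFGS and the better restricted
likelihood kept, because L-BFGS occasionally reports convergence at a
degenerate point.  Variance estimates below 1e-6 are reported as 0 with
a missing (NA) standard error — a Wald SE is meaningless on the
boundary.  Variance-component SEs are delta-method values on the
profiled scale converted to the data scale (ignoring uncertainty in
the residual scale).  When the joint Hessian is singular near a
boundary, fixed-effect SEs fall back to the model-based GLS covariance
(X′V⁻¹X)⁻¹ evaluated at the estimated components.  With
`include_random=False` the fit reduces exactly to OLS on the same
fixed design, which anchors the no-random-effects limit.

## Affect data-generating process

The generator draws (σ0i, σ1i) from a bivariate normal, σ3i and day
residuals from normals, builds latent day means from the model above
using the *realized* daily activity fractions of the simulated
schedules, adds occasion noise (SD 0.2) and item noise (SD 0.25), then
rounds to the 1–5 Likert grid.  Discretization and item noise attenuate
day-score variance relative to the latent means, so the generator also
exposes the pre-discretization means for calibration work.  Default
fixed effects and variance components describe a positive affect
dimension of children (intercept ≈ 3.98 on the 1–5 scale, slight
negative trend, near-null daily-activity effect, intercept variance
0.38, trend variance 9e-4, residual 0.297), with analogous per-factor
defaults for the other three dimensions; daily schedules target ~15% of
wear time active and ~21% of active time very vigorous, with wake
windows 7:00 ± 30 min to 21:00 ± 30 min — plausible magnitudes for
3rd/4th graders.  Activity fractions in the day-level panel generator
are truncated-normal (between-child mean 0.15, SD 0.05; within-child SD
0.05 by default), avoiding point masses at the support bounds.

## Calibration experiments and problem sizes

The calibration module fixes the Monte-Carlo designs: parameter
recovery runs 100 replicates of 100 children × 20 days at an
interior-valued DGP (γ30 = 0.3, slope variance 0.25, within-person PA
SD 0.15) — interior because a variance whose truth sits on the boundary
is estimated with one-sided error and a mean-vs-truth comparison is
ill-posed there; boundary behavior (0.00 (NA) reporting) is tested
separately.  The type-I error of the daily-activity Wald test uses 400
null replicates of 100 children × 10 days fitted with the fixed-effects
model.  The end-to-end null-world check runs the full raw-signal chain
on 10 children × 10 days per seed with ~7.5 h wake windows — above the
6 h valid-day bound, so every cleaning rule still operates — a size
chosen so multi-seed runs complete in minutes; single runs at
full-length (14 h) days behave identically up to wear-time magnitudes.

## Limitations

Synthetic gait is a clean sinusoid: real children's free-living data
will yield lower classifier accuracy, and the pipeline's near-perfect
recovery of scheduled activity fractions should be read as an internal
consistency check of the chain, not a validity claim.  The affect
instrument is simulated as conditionally independent items around a
factor mean — no response styles, no missingness mechanism beyond
whole occasions.  Non-wear detection relies on the classifier's
device-off class rather than count-threshold algorithms, so the
cleaning stage's behavior on real data depends on that class's field
accuracy.  Wald inference without df correction is anticonservative in
very small samples.
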