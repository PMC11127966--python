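# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `steplen`.

## Estimation model

### Regression on per-step features

The primary estimator maps a feature vector computed from one segmented step
of lower-back IMU data to the step length in cm. Five model families are
provided (`lr` linear regression, `tree` regression tree, `svm` RBF support
vector regression, `knn` k-nearest neighbors, `gbt` XGBoost gradient-boosted
trees); `gbt` is the default and the strongest in our experiments.
Deliberately, **no demographic or anthropometric inputs are used** — the
method is calibration-free by design, so height, weight, and leg length never
enter the feature set.

Hyper-parameters are grid-searched *per cross-validation fold* on that fold's
training subjects only, with an inner subject-wise split (default 3 inner
folds). Default grids: `gbt` depth {2, 4, 6} x learning rate {0.05, 0.2}
(200 trees); `tree` depth {2, 4, 6, 10}; `svm` C {0.1, 1, 10} x gamma
{scale, 0.1, 0.01}; `knn` k {1, 5, 15, 25}; `lr` none. Scale-sensitive
families (svm, knn) are standardized inside the estimator. Predictions are
clipped to a physiological envelope of [5, 150] cm; the clip is disabled for
window-distance targets, which live on a different scale.

All validation is **subject-wise**: `grouped_cv_split` assigns each
participant to exactly one test fold (sizes within one subject, stratified by
group when labels exist, deterministic given the seed), and the pipeline
asserts an empty intersection between train and test subjects in every fold.
Step-level rows from one subject are strongly correlated; splitting at the
row level would leak identity and inflate accuracy.

### Features

All features are computed from the low-pass-filtered, gravity-removed
acceleration over the step (or window) interval:

- time-domain statistics (mean, sd, min, max, range, RMS) per axis and for
  the Euclidean magnitude (24 features);
- the first 10 single-sided FFT amplitudes per acceleration axis
  (30 features). Steps vary in duration, so each step is linearly resampled
  to a fixed 128-sample grid before the FFT, making coefficient k comparable
  across steps; coefficient 0 is the (signed) mean, coefficients k >= 1 are
  amplitudes 2|X_k|/N. The fixed-grid convention is ours; for fixed-duration
  windows no resampling is needed;
- acceleration-magnitude energy: the mean squared Euclidean norm (1);
- double-integration displacements of the mediolateral and vertical axes:
  net displacement and peak-to-peak excursion, with drift control as
  described below (4);
- the step/window duration (1).

Sixty features total — a documented superset of the families the method is
built around (FFT coefficients, magnitude energy, double integration of the
ML and vertical axes). Forward stepwise selection then keeps the informative
subset: at each iteration every remaining candidate is scored by subject-wise
cross-validated RMSE of the selection model on (current set + candidate), the
best strictly-improving candidate is added (ties broken by feature-name
order), and selection stops at `max_features` or when nothing improves. The
accepted-RMSE path is non-increasing by construction. Selection is scored
with linear regression by default: it is orders of magnitude cheaper than
scoring with the boosted model and, in our cohorts, picks the same leading
features (vertical displacement range, vertical FFT amplitudes, duration).

### Inverted-pendulum baseline

During one step the body vaults over the stance leg like an inverted
pendulum of effective length `l`; the center of mass (CoM) rises by `h`
between initial contact and mid-stance, and chord geometry gives

    S = 2 * sqrt(2*l*h − h²),   with inverse   h = l − sqrt(l² − (S/2)²).

The estimator recovers `h` as the peak-to-peak vertical displacement from
double integration of the vertical acceleration within the step, then applies
the chord (times an optional correction factor, default 1). If `h >= l` the
geometry degenerates and the geometric maximum `2l` is returned with a flag.
Because the method is calibration-free, the pipeline's pendulum baseline uses
a *population* pendulum length (default 0.88 m ≈ 0.53 x a 1.66 m body
height) rather than per-subject leg lengths; per-subject lengths can be
passed when known.

### Drift control for double integration

A lower-back sensor never rests, so zero-velocity updates are unavailable.
Integration drift is controlled per step by an **endpoint-anchored linear
velocity detrend**: after integrating acceleration to velocity with zero
initial conditions, the straight line through the velocity's first and last
window values is subtracted, encoding the biomechanical boundary condition
that vertical CoM velocity is ~zero at each initial contact. For a constant
acceleration bias (e.g., residual gravity) the correction is exact. We use
the anchored form rather than a least-squares detrend deliberately: a
least-squares line fitted to one full sinusoidal period of velocity is *not*
zero and would corrupt the recovered excursion by tens of percent.

Window integrals include the exact (fractional-sample) window boundaries via
interpolation, so per-step quantities do not depend on where a step boundary
falls between samples.

### n-step averaging and gait speed

Estimates and references are averaged over consecutive, non-overlapping
blocks of n steps within a bout (trailing remainder dropped; n = 1 is the
identity; blocks never cross bout boundaries, keeping them independent). For
estimate = reference + iid noise of sd σ, block averaging contracts the RMSE
as σ/√n; the pipeline reports n ∈ {1, 3, 5, 10} by default. Averaging buys
accuracy at the cost of step-to-step variability information. Gait speed is
length/duration per step, or predicted distance / window length for the
non-segmented model.

### Non-segmented window model

As a segmentation-free variant, the same feature families are computed on
seeded random fixed-duration windows (1 s and 5 s by default); the target is
the reference distance traveled in the window, with partial steps pro-rated
by time overlap (our convention). Speed is predicted distance over window
length; accuracy is compared to the step model on speed RMSE.

## Preprocessing and segmentation

The low-pass filter is a windowed-sinc (Hamming) FIR, order 101 at 128 Hz,
cutoff 20 Hz, applied as a centered convolution with reflection padding:
linear phase with the group delay fully compensated, unit DC gain, <1%
ripple at 1 Hz, >40 dB attenuation at 50 Hz, and slow-event peak positions
preserved to within one sample. Gravity is removed by per-channel mean
subtraction over the bout — a calibration-free stand-in for orientation
estimation, adequate for level straight-line walking where the sensor's
vertical axis is roughly aligned with gravity.

Step segmentation works on the vertical channel: (1) the dominant step
frequency is the first sufficiently tall autocorrelation peak in the
physiological band 0.5–3.3 Hz; (2) initial contacts are local maxima above an
adaptive robust threshold (median + 0.5 x scaled MAD) separated by at least
0.6 step periods; (3) steps are the intervals between consecutive contacts,
kept only if 0.2–2.0 s long. A flat or aperiodic signal yields an empty
table, not an error. Detected steps are synchronized to a reference table by
greedy matching in order of increasing |start-time difference| (tolerance
0.25 s by default, ties toward the earlier reference step); on small
instances the greedy matching coincides with optimal assignment, which the
test suite verifies against an exhaustive oracle.

## The synthetic cohort

### What it emulates

`synthetic.simulate_bout` builds one straight-line bout from per-step draws
of length and duration. The vertical acceleration is the exact second
derivative of a per-step inverted-pendulum CoM trajectory
`y(t) = −(h/2) cos(2πt/D)` with `h = l − sqrt(l² − (S/2)²)` — CoM lowest at
each contact, highest mid-step, peak positive acceleration at the contact —
plus a heel-strike transient at every initial contact, a constant gravity
offset of +9.81 m/s², and optional white sensor noise on all channels.
ML/AP acceleration and the gyroscope channels carry low-amplitude step- and
stride-frequency oscillations (pelvic sway/rotation proxies) so the full
6-channel path is exercised. Group-level generators draw subjects around
clinically plausible means (e.g., older-adult-like ≈ 57.5 cm, Parkinson-like
≈ 56 cm with higher step-to-step variability, healthy-control-like ≈ 79 cm),
with pendulum length 0.53 x a drawn body height. Conditions rescale gait:
fast = x1.10 length / x0.92 duration; dual-task = x0.93 length / x1.3
variability — the directions seen on instrumented walkways; magnitudes are
free parameters. Identical spec + seed reproduces bouts bit-exactly;
cohort bouts use independent substreams spawned from the master seed.

### Numerical design of the ground truth

The simulator is also the test oracle, so the noiseless signal must be
*numerically* consistent with the estimators at 128 Hz. Three choices make
per-step double integration recover `h` to well under 1% relative error:

1. **Grid-aligned contacts.** Step durations are rounded to whole sample
   periods, so every contact falls exactly on a sample (physically: the
   walkway reference and the IMU share one clock). Otherwise the sub-sample
   contact phase, interacting with the acceleration jump at contacts,
   dominates the integration error (up to ~3%).
2. **Trapezoid-consistent contact samples.** When adjacent steps have
   different durations, the pendulum acceleration jumps at the shared
   contact. Interior contact samples store the mean of the two adjacent
   arcs' limits — the correct trapezoidal rendering of a jump at a node.
3. **A zero-footprint heel-strike transient.** The transient is a 5-sample
   discrete stencil A·[0.25, −0.75, 1, −0.75, 0.25] centered on the contact
   sample (≈40 ms at 128 Hz), amplitude 1.5 x the step's peak arc
   acceleration. The stencil is designed directly in discrete time so that
   each half contributes *exactly zero* trapezoidal velocity and displacement
   to the step window it falls in: the landmark is invisible to per-step
   double integration. Analytic pulse shapes (raised cosines and smooth
   zero-moment bumps) were tried first and rejected — at 128 Hz their
   sampled moments do not vanish, and the residuals (0.5–3% of `h`) broke
   the ground-truth contract. Like a real impact transient, the stencil's
   energy sits in the high-frequency band and is largely removed by the
   20 Hz filter; segmentation keys on the (filtered) pendulum-arc peak at
   the contact.

### What it does not emulate

Turning, stops, stairs, freezing episodes, slopes; soft-tissue and mounting
artifacts; orientation drift (the sensor frame is assumed aligned, so gravity
removal by mean subtraction is exact here but only approximate on real
devices); left/right asymmetries beyond a simple alternating length offset;
and any deviation of true CoM motion from the inverted-pendulum relation —
in real cohorts that model error is why the pendulum baseline degrades far
more than it does here. Passing tests on this simulator therefore validate
the pipeline's mechanics, determinism, and statistical protocol, not
clinical-grade accuracy on real patients.

## Agreement statistics

- RMSE in cm; relative error RA = 100 · mean(|est − ref| / ref) % (the
  "relative to the reference" convention is ours; the quantity tracks RMSE
  but rescales with mean step length).
- ICC(2,1): two-way random effects, absolute agreement, single measure, from
  the explicit two-way ANOVA decomposition with k = 2 raters; degenerate
  zero-variance input returns an undefined flag (`None`) rather than NaN
  arithmetic. The implementation is cross-checked against pingouin in the
  test suite. Reliability bands: <0.5 poor, 0.5–0.75 moderate, 0.76–0.9 good,
  >0.9 excellent.
- Bland–Altman: mean difference ± 1.96 x sd (ddof = 1); LoA width is exactly
  3.92 sd.
- Correlation: Pearson r plus an identity-line R² (1 − SSres/SStot with the
  estimate as the prediction of the reference) — the agreement-relevant R²,
  which penalizes bias that r ignores.
- One-way ANOVA across averaging levels, computed on per-fold RMSE values
  (5 values per level); zero within-group variance with differing means
  returns an infinite-F flag. Per-fold aggregation throughout is mean ± sd
  over the cross-validation folds.

Reports are assembled per stratum (overall, group, condition, averaging
level); empty strata are omitted with a logged notice; serialization is JSON
plus a Markdown table.

## Problem sizes and defaults

The canonical synthetic study cohort (`pipeline.default_study_cohort`) is 60
subjects (20 each of older-adult-like, Parkinson-like, MCI-like), three
conditions, 12 steps per bout (2,160 steps), sensor noise 0.3 m/s², 5
subject-wise folds, stepwise selection capped at 10 features for the
pipeline runs — sizes chosen so a full end-to-end run completes in a couple
of minutes on a single CPU while keeping >400 steps per fold. The selector's
`max_features` default in the library API is 34. Averaging levels default to
{1, 3, 5, 10}; window lengths to {1 s, 5 s}; all lengths are cm at I/O
boundaries and SI units internally.

## Known limitations

- The simulator's pendulum-exact vertical channel makes the pendulum baseline
  unrealistically competitive at low noise; the pipeline deliberately denies
  it per-subject calibration to reflect field conditions.
- Gravity removal by mean subtraction assumes a roughly upright, static
  sensor orientation per bout.
- Greedy synchronization is not globally optimal for pathological timing
  patterns (verified equivalent to optimal assignment only on small
  instances).
- The stepwise selector refits one model per candidate per fold per
  iteration; with the linear scorer this is fast, but scoring with `gbt`
  directly is expensive and left to the user.
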