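# Methods

This note documents the models, parameter choices and numerical
conventions behind `prestim`, and what the synthetic benchmark does and
does not establish.

## Generative model of a session

A session follows the recognition-threshold paradigm: 4 object
categories × (5 real + 1 phase-scrambled) images × 15 repetitions = 360
trials (300 real, 60 scrambled) in 10 blocks, presented in a seeded
random order so the forthcoming category is unpredictable.  Inter-trial
timing uses truncated-exponential blank periods (3–6 s before, 2–4 s
after the ~67-ms stimulus), which only matters for placing epochs and
the pupil trace on a common timeline.

Two latent processes are drawn per trial, independent of the stimulus
sequence:

* **General latent** `g ~ N(0, 1)`, i.i.d. across trials by default.  An
  AR(1) option (`latent_ar1`) exists for robustness studies, off by
  default because the decision variables of the fitted decoders show no
  across-trial autocorrelation in the regime being modeled.
* **Specific latent**: a preferred category, uniform over the four
  categories.  `match` indicates that it equals the (source) category of
  the trial's image.

**Recognition** is Bernoulli under a probit model

    P(yes) = Φ( b0 + b_real·is_real + b_g·g + b_match·match·is_real
                + b_match_scr·match·(1 − is_real) )

The probit link is deliberate: it puts the coefficients on the
signal-detection evidence axis, so the general latent is *exactly* a
criterion shift (equal displacement of Z(HR) and Z(FAR), no d' change)
and the match effect is *exactly* a sensitivity change.  With a logistic
link the same construction leaks a spurious d' effect into the general
split of order +0.1–0.2, because equal logit shifts are not equal probit
shifts at different base rates.

The match effect is a **discriminability boost**: a valid spontaneous
category prediction both raises recognition of a real image
(`b_match > 0`) and lowers spurious recognition of a scrambled one
(`b_match_scr < 0`).  This is the generative reading of "a larger
distance between the internal representations of object and noise": a
pure hit-rate boost would mechanically drag the criterion along
(Δc = −ΔZ(HR)/2) with the same t-statistic as the d' effect, and no
double dissociation could exist.  `b_match_scr` (−0.9) is smaller in
magnitude than `b_match` (1.2) because the false-alarm side of the
criterion computation is convexity-biased at the design's small
per-group scrambled counts (~15–17 trials); the pair was calibrated so
that the planted specific effect is criterion-neutral in expectation at
the default design size (measured Δc = +0.006 ± 0.237 per subject).

**Sensor epochs**: each time sample of trial *t* is

    x_t = gain_g·w_g·g_t + gain_cat·W_c[pref_t] + drift·(t − block_start) + ε

with `w_g`, rows of `W_c` unit-norm random patterns (orthonormal by
default; `pattern_overlap` mixes in a shared component), ε i.i.d.
Gaussian per sensor and sample (`noise_sd = 1`), and a small linear
drift per block (0.005 units/s) for the detrending stage to remove.
Epochs are 2 s at 100 Hz over 64 sensors by default (desk scale); the
recording-faithful 272 sensors / 1200 Hz are reachable through the same
fields but are not the tested configuration.

**Reports**: category reports hit the stratum accuracy targets
(86.5% / 40.1% recognized / unrecognized real; 51.9% / 31.6% scrambled,
scored against the source image's category), with a
`report_bias_strength = 0.15` chance that the report is captured by the
trial's preferred category instead (the correct-report probability is
compensated so the marginal accuracy stays on target).  The preference
capture is what lets the specific process bias categorization of both
real and scrambled images.

**Pupil**: the pre-stimulus diameter holds `pupil_gain·g` through each
2-s window (linear interpolation between trials), plus white measurement
noise (0.1) and square blink drops (depth 5, 150 ms, 4/min) that exceed
the 3.6-unit detection threshold.

### Calibration of effect sizes

`b0 = −0.8`, `b_real = 0.4`, `b_g = 0.7`, `b_match = 1.2`,
`b_match_scr = −0.9`, `gain_g = 0.16`, `gain_cat = 1.0` were calibrated
once against the paradigm's observed operating point and then frozen:
real-image recognition ≈ 0.47, scrambled ≈ 0.21, recognition-decoding
AUROC ≈ 0.65, category-decoding AUROC ≈ 0.55 in recognized trials and
≈ 0.51 in unrecognized trials, and hi/lo group differences of the size
the dissociation analysis reports.  The planted match effect is at the
upper end of what the observed operating point suggests; it is chosen so
that the d' contrast is detectable with power ≥ 0.8 in a 24-subject
cohort, which the analysis pipeline is required to achieve on data that
truly contain the effect.

## Preprocessing

* Per-block linear detrend: ordinary least squares line (with
  intercept) per sensor over the block's concatenated samples placed at
  their true session times; no frequency-domain filtering anywhere, so
  nothing can leak backwards from the post-stimulus window.
* Brain state: arithmetic mean over the half-open window
  `[onset − 2 s, onset)`; half-open to exclude the onset sample itself.
* Blinks: a sample is blink-affected when the diameter is ≥ 3.6 units
  below the median of the preceding 100 ms (the baseline freezes at
  blink onset so long blinks do not swallow their own reference — the
  baseline rule is a documented choice, configurable); intervals are
  padded ±40 ms and merged.  Trials with a blink during stimulus
  presentation are dropped; trials whose pupil window is fully
  blink-affected get a missing pupil mean and leave the sensor analyses
  untouched.

## Decoding

L2-penalized logistic regression, C = 1, intercept unpenalized.
Features are z-scored per sensor with statistics of the training rows
only (penalized fits are scale-sensitive; the data generator gives
sensors a common scale but real recordings do not).  Binary fits use
lbfgs, multiclass fits Newton-CG on the multinomial objective, both
deterministic, tolerance 1e-6, ≤ 1000 iterations.  The leave-one-out
inner loop for binary problems runs an in-package damped Newton solver
of the identical objective, warm-started per fold from the full-data
solution — an exact-refit optimization (agreement with per-fold
scikit-learn fits is asserted in the tests), not an approximation.

AUROC: binary scores use the rank (Mann–Whitney) form, ties counting
one half.  Multiclass scores build a one-vs-rest ROC per class from that
class's probability column, interpolate each curve onto a common
101-point false-positive-rate grid, average vertically and integrate by
trapezoid.  Interpolation between operating points is piecewise-linear
with vertical segments collapsed to their upper point: this is the
convention consistent with half-credit ties (an all-tied prediction
scores exactly 0.5; a right-continuous step rule, available as
`interpolation="step"`, would score it near 0).  Averaging the
per-class areas instead of the curves is available as `average="auc"`
for sensitivity checks.

Cross-condition decoding fits once on the training condition and scores
the untouched test condition; identical train/test sets or overlapping
trial indices raise.  Activation patterns are `A = Σx·β` with Σx the
empirical covariance of the decoder's (standardized) training data;
group patterns are element-wise medians across subjects.

## Inference

The group permutation test shuffles labels across trials within subject,
recomputes each subject's score and averages; `p = #{permuted ≥ actual}/B`
as published (ties count against the actual score; p = 0 is possible and
reported as such, with the (k+1)/(B+1) smoothed estimate alongside).
Each subject's permutation stream derives from (seed, subject id), so
the p-value is invariant to subject ordering.  B defaults to 1000 for
faithful runs and to small values in desk-scale configurations.  Paired
comparisons use two-tailed Wilcoxon signed-rank (zero differences
dropped; all-zero input reported degenerate) for bounded variables and
paired t for d' and criterion.

## Behavioral analyses

SDT metrics are computed per subject and then averaged — the order
matters because c(mean HR, mean FAR) ≠ mean c.  Ties in both split rules
go to the low group (strict inequalities).  The entropy median split is
rank-based with ties broken by trial order, so group sizes differ by at
most one.  The ≥ 5 recognized-scrambled-trials inclusion rule applies to
scrambled-decoding analyses only and is configurable
(`min_recognized_scrambled`).

## What the synthetic benchmark shows — and what it does not

Passing tests establish that the pipeline *recovers known structure*:
chance-level calibration on null data, correct closed forms, and the
double dissociation when (and only when) the corresponding latent is
planted.  The generator emulates the design counts, the behavioral
operating point, pattern-expressed latents and pupil coupling; it does
**not** emulate oscillatory structure, sensor covariance of real MEG
noise, eye-movement or cardiac artifacts, head motion, learning or
fatigue trends beyond a linear drift, or history effects (a previous-
report term exists but is off by default, consistent with treating
serial dependence as separate from the spontaneous processes).  Success
here therefore validates the analysis logic, not any claim about real
recordings.

Two residual finite-sample effects are worth knowing.  Leave-one-out
AUROC carries a small pessimistic bias at low trial counts (each fold's
training set is slightly anticorrelated with its held-out label); it is
negligible at the 300-trial scale the pipeline targets.  And the crossed
dissociation contrasts (d' under the general split, c under the specific
split) are not exactly null in finite samples — Z-transforms of small-
count rates are convexity-biased and the splits are selected on
cross-validated probabilities — so their empirical rejection rate at
α = 0.05 sits near 10% rather than 5% at the default design size.  The
acceptance suite bounds them at ≤ 5 rejections in 20 experiments
(nominal plus Monte-Carlo slack).

## Problem sizes of the shipped checks

Desk-scale defaults keep every stage within an interactive budget:
sessions of 360 trials × 64 sensors × 200 samples; 50 null sessions for
ROC calibration; 20 experiments × 24 subjects per planted configuration
for the dissociation power analysis; 8 experiments × 10 subjects for the
pupil linkage; permutation tests at reduced B in examples.  All
randomness flows from explicit seeds through independent child streams,
so any number in this repository can be regenerated exactly.
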