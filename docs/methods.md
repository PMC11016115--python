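# Methods

This note documents the models, estimators and numerical choices behind
`reachadapt`, what the synthetic-data generator does and does not emulate,
and the problem sizes at which the validation suites run.

## Behavioural model

### State-space learner

Trial-by-trial adaptation follows the single-rate linear state-space model.
With `r_t` the cursor rotation on trial `t` (counterclockwise positive),
`x_t` the internal state expressed in hand-angle degrees, and the
compensatory sign convention (positive hand angle opposes the rotation):

    e_t     = r_t − x_t        (cursor error)
    x_{t+1} = A x_t + B e_t

`A ∈ [0, 1]` is the retention rate, `B ∈ [0, 1]` the adaptation rate.  Under
constant rotation the state converges to `x* = B r / (1 − A + B)`; with the
default gradual schedule (0.2°/trial to a 20° ceiling: zero through the
30-trial baseline, ramp indexed `min(0.2 (t − 1), 20)` over the 120
adaptation trials so the ceiling is reached on trial 101, zero through
washout) the state tracks the ramp with a lag set by `1 − A + B`.

### Estimation

`A` and `B` are estimated per subject × task by ordinary least squares of
`x_{t+1}` on the two regressors `[x_t, e_t]` with **no intercept**, where the
observed hand angle stands in for the state and `e_t = r_t − x_t` is formed
from the observations.  A one-regressor formulation cannot identify two
coefficients, so the two-regressor design implied by the update equation is
used; an optional intercept is available for sensitivity analysis
(`fit_intercept` in the analysis config).  R² is the ordinary coefficient of
determination of the one-step-ahead predictions.  Excluded trials drop
pairwise: `(t, t+1)` enters only if both trials survived exclusion.  A
rank-deficient design (e.g. an identically zero series) raises an
`UnidentifiableModelError` rather than returning arbitrary coefficients.

Two distinct noise regimes matter here:

- **State noise** (`simulate_state_space(noise_sd=...)`): noise enters the
  update itself, the regression is correctly specified, and estimates are
  unbiased — 500 replicates at `A = 0.9, B = 0.3`, 1° noise and 120 trials
  recover both means within ±0.05 (acceptance suite).
- **Motor (observation) noise** (the behaviour generator): the executed hand
  angle is `h_t = x_t + ε_t` and the learner updates from the cursor error it
  actually experiences, `e_t = r_t − h_t`.  Regressing the observed series
  then estimates the best linear one-step predictor of the noisy
  observations, not `(A_true, B_true)`: the noise appears in both regressors
  (errors-in-variables), which biases the coefficients while leaving the
  between-task ordering intact.  This mirrors the situation with real data,
  where the same regression is applied to observed angles; the package
  reports what the method measures rather than re-calibrating the generator
  to make the two coincide.

### Kinematic measures

Trajectories are sampled at 60 Hz and low-pass filtered with a zero-phase
4th-order Butterworth at 20 Hz (forward–backward, so no lag bias in the
peak-velocity sample; the effective magnitude response is squared).
y-velocity is the finite-difference derivative (central, one-sided at the
edges).  Then:

- **hand angle** — signed angle between the start→target ray and the
  start→hand ray at the sample of maximal y-velocity, positive in the
  compensatory direction;
- **RT** — go signal to the first sample with y-velocity strictly above
  20 mm/s;
- **MT** — duration of the contiguous supra-threshold interval containing
  the global velocity peak (robust to brief pre-go jitter crossings).

Trials whose velocity never crosses the threshold are excluded with a reason
code, never imputed.

### Outlier rule

A trial is excluded when its hand angle deviates from a centred 5-trial
moving mean (excluding the trial itself, window shrunk at the series edges)
by more than 3 standard deviations, where the SD scale is the ddof-1 standard
deviation of the full per-subject × task hand-angle series.  The choice of SD
scale is forced by arithmetic: with a within-window SD the rule is degenerate
— including the trial, `|x − mean|` cannot exceed `(n−1)/√n ≈ 1.79` SD for a
5-point window, so nothing is ever flagged; excluding it, the 3-df SD
estimate flags ≈7% of pure-noise trials, orders of magnitude above the
observed exclusion scale.  The series-level SD flags gross errors (tens of
degrees) while passing ordinary motor noise, reproducing the observed scale
of ~2 exclusions in 2880 trials, which the generator exercises by injecting
two ±40° outliers per full dataset (configurable).  Whether the window is
centred or trailing is not specified by the source analysis; centred was
chosen and flags are computed once on the raw series.

## Synthetic-data generator

The generator's defaults are the study conditions: 8 subjects × 2 tasks
(visually-guided, memory-guided) × 180 trials in 6 blocks of 30; targets
i.i.d. uniform on [−10°, 10°] at 8 cm; the gradual rotation above; cursor
sampling at 60 Hz; 20-channel EEG at 500 Hz.  One top-level seed fans out to
fixed named substreams (design / behaviour / EEG / decoding permutations), so
identical configs give byte-identical artifacts and stages can re-run
independently.

Per-trial behaviour: reaction times are truncated-normal per task (visual
0.30 s, memory 0.40 s, SD 0.05 s — the paradigm constrains only the
direction of the difference, so the means are configuration parameters);
movement duration 0.35 s with 0.02 s jitter; the reach is a minimum-jerk
position profile of 100 mm (crossing the 80 mm feedback ring at ~69.5% of
movement time, "shooting through" the target) along the direction
`target − h_t`.  In the memory-guided task the go signal follows target
offset by 2.2 s (0.2 s presentation + 2 s delay).  Trial slots are long
enough that every event marker has ≥2.5 s of signal on both sides.

EEG: each channel is independent 1/f noise (exponent 1, 10 µV rms; the
spectrum is flattened below 0.1 Hz).  Declared effects multiply the
band-passed component of each effect channel's own background by
`1 + g·w(t)` around the aligned event, where `w` is a Tukey (flat-top,
Hann-tapered) envelope over the effect window.  The scalar gain `g` is
calibrated by a forward model of the analysis chain — the burst's relative
band-power profile is smoothed by the wavelet's temporal power envelope
(Gaussian, σ_t/√2), weighted across frequency by the Butterworth transfer of
the burst filter under each wavelet's spectral window against the 1/f
background, and passed through the same inclusive baseline windows and
edge-validity rules as the analyzer — so the **measured** band-averaged dB
difference between tasks equals the configured value in expectation.  Without
this calibration the wavelet's temporal smearing (σ_t ≈ 0.48 s at 1 Hz)
contaminates the short pre-feedback baseline and dilutes the window, and a
nominally 3 dB burst measures ≈1.4 dB.  The default effects are a +3 dB
post-feedback (0–1 s) parietal (P3/Pz/P4) delta increase and a −2 dB
pre-movement (−1–0 s) C3/Fz beta difference, both "visual minus memory".
Negative differences add power to the memory task rather than attenuating the
visual one.

What the generator does **not** emulate: ocular/muscle artifacts and line
noise (the artifact-removal hook is the identity), inter-channel covariance
and volume conduction, non-stationary backgrounds, feedback-control
corrections inside a reach, explicit/strategic re-aiming, and savings across
blocks.  Passing tests therefore validate the analysis chain and its
calibration, not claims about real-EEG robustness.

## EEG analysis

Preprocessing: zero-phase 0.05–100 Hz band-pass (applied as separate
high-pass and low-pass sections — one digital band-pass spanning four
decades is numerically ill-conditioned) plus a 50 Hz notch (Q = 30).
Epochs are −2…+2 s around reach onset or feedback onset (right edge
exclusive: exactly `4·fs` samples); markers too close to a recording edge are
dropped with a logged warning.

Time–frequency power uses complex Morlet wavelets at 1–30 Hz in 1 Hz steps,
sampled every 50 ms (the sampling rate must be a multiple of 20 Hz so the
bin grid is exact and bit-stable).  A literal fixed 200 ms analysis window
cannot resolve 1 Hz, so two modes are exposed: the default `fixed_cycles`
mode (3-cycle wavelets, σ_t = 3/(2πf)) and a `fixed_window` mode with a
constant 200 ms Gaussian envelope (σ_t = 40 ms) at all frequencies.  Wavelets
are zero-mean corrected and scaled so a sinusoid of amplitude `A` yields
power `A²`.  Bins within 2σ_t of an epoch edge are set to NaN and excluded
from every average — never zero-filled; at 1 Hz this leaves a single valid
baseline bin for reach-aligned data, which is accepted rather than silently
widening the baseline.

dB conversion is `10·log10(P / mean baseline P)` per trial, channel and
frequency, with baselines −1500…−1000 ms (reach-aligned) and −100…0 ms
(feedback-aligned); whether the source analysis baselined per trial or on the
trial average is unstated — per-trial was chosen, and since dB values are
averaged arithmetically afterwards, band and trial averaging commute.  Band
averages use inclusive edges (delta 1–4, theta 4–8, alpha 8–13, beta
13–30 Hz; a shared edge bin belongs to both bands) over the group's
electrodes (parietal = P3/Pz/P4).

## Decoding and inference

Features at each 50 ms bin are the dB values of one band at one electrode
group (3 features for parietal, 1 for C3 or Fz), over the second before
reach onset or the second after feedback (21 bins).  The classifier is a
linear maximum-margin SVM with fixed C = 1 and within-training-fold feature
standardization, evaluated by leave-one-subject-out cross-validation:
accuracy pools the 2n held-out predictions.  Ties in the decision value
predict the first label, keeping runs reproducible.

The null distribution flips each subject's label pair independently with
probability ½ (preserving the paired structure) and recomputes the full LOSO
analysis; `n_perm = 1000` by default.  The chance level is the median of the
per-bin null.  Multiplicity over time is handled by the max-statistic: the
null statistic is each permutation's maximum accuracy over the window and the
threshold is its 95th percentile, applied to every bin; an uncorrected
per-bin mode exists for comparison.  Significance requires the true accuracy
to strictly exceed the threshold.  Fits run through scikit-learn's libsvm
binding via a thin wrapper that extracts the primal weights directly
(permutation suites need ~10⁶ fits of 14-sample problems); the wrapper is
asserted equal to `SVC(kernel="linear")` decision values in the test suite.

## Statistics

Paired t tests are two-sided on `df = n − 1`.  Cohen's d defaults to
`d_z = mean(diff)/SD(diff)`; the `d_av` convention (mean difference over the
average condition SD) is also implemented and the convention used is recorded
in the output, because the two differ and neither can be inferred from the
reported values alone.  The two-way repeated-measures ANOVA implements the
balanced fully-within sums-of-squares decomposition with subject-by-factor
error strata, no sphericity correction (so an 8 × 2 × 4 table gives task
(1, 7) and block (3, 21)), and partial η² = SS_effect/(SS_effect+SS_error);
it is implemented directly because partial η² needs the per-stratum error SS,
and cross-checked against an independent brute-force decomposition and
against `pingouin` in the tests.  p-values are computed but are never used as
calibration surfaces (they are data-dependent).

## Validation problem sizes

The calibration suites run at sizes chosen to keep the full test run around
seven minutes on one CPU while leaving Monte-Carlo error well inside each
tolerance: parameter recovery uses 500 replicates of 120 trials; decoder
chance uses 200 label-independent datasets (tolerance ±0.05); family-wise
error uses 200 outer replicates × 200 permutations over a 21-bin window
(bound 0.05 + 0.03 Monte-Carlo allowance); the end-to-end effect-recovery
study uses 50 scaled experiments (8 subjects, 6 blocks of 3 trials, the
parietal montage, 200 permutations) for the +3 dB detection rate (>90%
required) and 25 null experiments for the false-positive rate
(≤ 0.05 + 2 binomial SEs).  The dB round-trip tolerance is ±0.5 dB on the
band-averaged difference.  The acceptance script re-derives the same
quantities at comparable sizes in about two minutes.

## Known limitations

- The generator's effect calibration assumes the analyzer's default wavelet
  settings; analysing with a different mode or cycle count recovers a
  systematically different (documented, deterministic) dB value.
- Behaviour-level fits estimate predictive, not generative, rates under
  motor noise (see above); only the state-noise pathway is a parameter-
  recovery instrument.
- With few subjects (≲4) the paired permutation null is coarse (2ⁿ flip
  patterns) and perfect accuracy may not be significant.
- The rm-ANOVA requires a complete balanced design; missing cells raise
  rather than being imputed.
- EEG channels are simulated independently; analyses that depend on
  cross-channel structure (e.g. spatial filters) would not be stressed by
  this generator.
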