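# Methods

This note documents the models, estimators and numerical choices behind
`tgdecode`, and what the synthetic validation studies do and do not show.

## The analysis problem

A retro-cue MEG experiment yields, per subject, two paired epoch segments:
a *perception* segment time-locked to the first stimulus (a face or a
house) and an *imagery* segment time-locked to the cue instructing the
subject to imagine one of them, plus a 2-channel eye-tracker segment and a
per-trial vividness rating on a [-150, 150] scale. The scientific
questions are *when* stimulus category can be decoded from the sensor
array, whether the underlying representation is stable or changing
(temporal generalization), and where the discriminating field pattern
originates (source projection).

## Decoding model

At each time point *t* the sensor vector (after a centred 30 ms boxcar
average) is classified with a two-class linear discriminant:

    w = C_γ⁻¹ (μ₁ − μ₀),   b = −wᵀ(μ₀ + μ₁)/2,
    C_γ = (1 − γ) C_w + γ (tr C_w / p) I

where `C_w` is the pooled within-class covariance of the training trials
and γ the shrinkage intensity toward the scaled identity. With ~270
sensors and ~170 training trials `C_w` is ill-conditioned; γ = "auto"
(default) uses the Ledoit–Wolf estimate computed from the class-centred
residuals, and a fixed γ ∈ [0, 1] can be forced instead. For two
homoscedastic Gaussian classes the Bayes accuracy is Φ(d/2) with *d* the
Mahalanobis distance between class means; `oracle_accuracy` evaluates it
and anchors the calibration tests.

Cross-validation is stratified 5-fold on trials (seeded, shuffled). One
fold partition drives *everything* computed for a subject and condition
pair: the diagonal timecourse, the full temporal generalization (TG)
matrix and cross-condition matrices all reuse the same folds, so
diagonal/off-diagonal comparisons are paired and partition noise cancels.
Training folds are class-balanced by random removal from the majority
class; test folds are scored as they come (pooled proportion correct is
chance-calibrated without balancing). Cross-condition decoding exploits
the paired trial structure: the classifier trains on the training trials
of one segment and is tested on the *held-out* trials of the other, which
removes the optimistic bias that shared trial identity would otherwise
introduce.

## Group inference

Decoding maps (time, or time x time) are tested across subjects with
cluster-mass permutation tests: pointwise t statistics thresholded at the
two-tailed p < 0.05 quantile, supra-threshold points merged under 1-D
adjacency / 2-D 4-connectivity, t values summed per cluster (positive and
negative clusters formed separately). The null is built from 1000
sign-flips of the subject-level deviations (or group relabellings for
two-group tests), recording the extreme cluster mass per permutation.
By default each observed |mass| is ranked against the per-permutation
maximum over *both* tails (`tail_mode="joint"`), which controls the
two-tailed family-wise error at the nominal level — measured 0.045 on 200
null groups. The alternative `tail_mode="separate"` ranks each sign
against its own tail only; because both tails are then tested at the full
α, its any-cluster false-positive rate is close to 2α (measured 0.09) —
it is provided for comparability with pipelines that use that convention.
Monte-Carlo p values include the observed statistic, `p = (1 + #{perm ≥
obs}) / (n_perm + 1)`, so p is never 0.

The **temporal specificity index** asks, for each time *t* inside the
window where diagonal decoding is significantly above chance, what
fraction of other training times *t′* in that window decode time *t*
significantly *worse* than the matched classifier: a one-tailed paired
comparison of A(t,t) − A(t′,t) across subjects, cluster-corrected along
*t′* by default (`method="pointwise"` gives the uncorrected variant).
The point *t′* = *t* is excluded from the numerator and breaks cluster
adjacency; the denominator is the window size. Values near 1 mean
representations usable only at their own moment; values near 0 mean one
stable representation.

Vividness analyses: subjects are ranked by mean vividness and split at
the median (odd N drops the middle subject; ties are resolved by subject
order with a warning), and the two groups are compared with the two-group
cluster test. Scalar correlations use Pearson r with a permutation p;
correlations of a subject scalar with subject maps feed pointwise
correlation t statistics into the same cluster machinery.

## Source projection

The face-minus-house difference ERF is projected through LCMV beamformer
filters `W = (Lᵀ C⁻¹ L)⁻¹ Lᵀ C⁻¹` built per source from a rank-reduced
leadfield (the orientation along the surface normal, to which MEG is
essentially blind, is projected out, leaving an orthonormal tangential
2-basis) and a data covariance shrunk toward the scaled identity with
γ = 0.01. Filters satisfy the unit-gain constraint `W L = I₂` to machine
precision and are invariant to covariance scale. Source power is the
windowed mean squared norm of the 2-D dipole moment. Because a norm is
noise-inflated, the bias is estimated by flipping the sign of a random
floor(n/2) of all trials (cancelling the stimulus-locked component),
averaging as a pseudo difference between the flipped half and the rest —
this matches the sampling variance of the class-difference ERF, so the
corrected quantity `(raw − noise) / noise` is zero-centred at inactive
sources — projecting, and averaging the windowed power over (default
1000, validation studies 100) permutations. Corrected power is averaged
per atlas region, then across subjects. The subtract-then-divide order
makes the result a unitless excess-over-noise-floor ratio bounded below
by −1. Imagery segments can be low-pass filtered (zero-phase Butterworth,
30 Hz) before source analysis.

## Synthetic data generator

Class information enters as signed spatial patterns: trials of class 1
add `+snr · e_k(t) · u_k` per pattern, class 0 adds the mirror image, on
top of i.i.d. unit-variance sensor noise (optionally equicorrelated
across sensors to exercise shrinkage). Chance is therefore exactly 0.5
and the per-time Bayes accuracy is Φ(snr · e(t) · √n_avg) for unit-norm
patterns (n_avg = smoothing-window length). Scenarios fix the envelopes
`e_k`:

- **sequential** — `n_patterns` orthonormal patterns in disjoint
  consecutive windows with Hann-shaped envelopes. Transient evoked
  components wax and wane; a boxcar would make every classifier inside a
  window exactly equivalent, which both is unrealistic and makes the
  specificity index degenerate at the window level.
- **sustained** — one pattern, boxcar plateau.
- **reactivation** — one pattern active in two disjoint windows.
- **jittered** — sequential dynamics with a per-trial onset shift drawn
  half-normal, scaled so the SD equals `jitter_sd_s`. The shift models
  the variable latency of a cue-triggered process and is therefore
  non-negative: a process cannot begin before the cue that triggers it,
  and a symmetric zero-mean shift would *advance* the measured group
  onset (early-shifted trials leak signal into pre-onset time points)
  instead of delaying it. `jitter_dist="normal"` restores a symmetric
  shift for comparison.
- **null** — noise only.

The imagery segment reuses a configurable subset of the patterns
(`imagery_patterns`) in one broad sustained window at 0.4 of the
perception amplitude — mirroring the finding that imagery re-expresses
late perceptual patterns at once, weakly, rather than replaying the
sequence. Trials are paired across segments (same order, same labels), as
the retro-cue design implies. Vividness ratings are drawn per trial
around a subject mean that can be correlated with the subject's SNR
(`vividness_snr_corr`) to give median splits something to find. Defaults
are the study conditions: 270 sensors, 300 Hz, 107 trials per class and
condition, 25 subjects, imagery at 0.4 x perception SNR.

The synthetic forward model (`make_leadfield`) places sources on an
upper hemisphere (radial surface normals) and sensors on a surrounding
cap; gains are spatially smoothed random fields with a Gaussian distance
fall-off, orthonormalized per source so every gain block is
well-conditioned (physical forward models have well-conditioned
orientation triplets; near-parallel orientation fields would inflate that
source's beamformer noise floor through the unit-gain constraint and
suppress its corrected power). Atlas regions are contiguous spatial
patches (k-means on source positions). In source-space mode the
generator draws the class patterns as tangential dipoles at distinct
sources through a *shared* template leadfield per group, so atlas regions
correspond across subjects, while moment directions remain
subject-specific.

What the generator does **not** emulate: realistic ERF waveshapes beyond
the parameterized envelopes, 1/f sensor noise spectra, artifacts (eye,
cardiac, movement), head geometry or volume conduction physics, and
between-subject anatomical variability. Passing recovery tests therefore
demonstrates that the estimators are correct and calibrated under the
stated signal model — not that any particular real dataset would yield
the same timecourses.

## Validation studies and problem sizes

The validation experiments (`tgdecode.experiments`, also driven by
`scripts/acceptance.py`) run at a reduced demonstration scale chosen so
the full battery completes in minutes on one CPU: scenario-recovery
studies keep the full 270-sensor array — the high-dimensional regime is
what makes training-time SNR matter — but sample at 100 Hz over a
[-0.1, 0.8] s epoch with 15 subjects; calibration studies whose outcome
is dimension-independent (chance level, FWER, jitter) use a 40-sensor
array; the beamformer study uses 50 sources, 80 sensors and 20
group-level replicates. Statistical parameters (1000 permutations for
observed tests, 500 for the 200-replicate FWER study, cluster-forming
p < 0.05) are not scaled down.

Known structural property of the specificity index worth stating: with K
equal-duration sequential patterns the index cannot exceed
1 − (own-window span)/(window) on average — about (K−1)/K plus a partial
own-window term from envelope peaking. For K = 3 the measured average is
~0.73–0.75 (peaks reach 0.9+; low-amplitude shoulder times, where
accuracies compress toward chance, drag the window mean). High average
specificity (> 0.8) requires either more, shorter-lived patterns or
restricting the average to high-SNR times.

## Numerical and degenerate-input choices

- Smoothing windows are forced to odd sample counts so "centred" is
  exact; epoch edges use the truncated-window mean (no padding invents
  data). 30 ms at 300 Hz is 9 samples (already odd).
- Downsampling low-passes at 0.4 x the target rate (8th-order zero-phase
  Butterworth) before decimation; the factor must be an integer.
- Sample instants, in seconds relative to event onset, are points, not
  bins; all windows are half-open `[start, end)`.
- Decision ties (`wᵀx + b = 0`) predict class 0; zero-variance features
  and single-class training sets raise errors rather than degrade.
- Cluster tests with constant maps produce a 0/0 t statistic, treated as
  t = 0 (no clusters) rather than NaN.
- All randomness flows through explicit integer seeds; the pipeline
  derives per-stage/per-subject seeds from the master seed via
  `SeedSequence`, so reruns are byte-identical and stages can be rerun
  independently.

## Limitations

- The LDA assumes shared class covariance; the generator honours this,
  real data need not.
- The specificity index inherits the power of the paired cluster test;
  with few subjects it underestimates specificity (significantly-lower
  points go undetected), never overestimates it.
- Beamformer localization is reported at atlas-region granularity;
  adjacent sources within ~the leadfield fall-off share gain subspaces
  and single-source attribution at the grid level is not claimed.
- The eye-tracker control and vividness analyses are mechanical
  re-applications of the decoding and cluster machinery; their synthetic
  effects (gaze offsets, SNR-coupled vividness) are deliberately simple.
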