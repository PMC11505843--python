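# Methods

This note documents the models, calibrations and numerical choices behind
`posturemg`: what the synthetic generator simulates, how the analysis
pipeline measures it, where the two interact, and what a green test does and
does not establish.

## 1. Signal conditioning

EMG channels are demeaned, full-wave rectified and low-pass filtered with a
4th-order Butterworth at 200 Hz; the shoulder angle is low-pass filtered at
20 Hz.  Both filters are applied **zero-phase** (forward-backward,
`sosfiltfilt`).  Phase handling is an implementation choice: epoch timing is
the core of the analysis and a causal filter would delay every onset by the
group delay; the cost is that stopband attenuation doubles relative to the
nominal single-pass response.  Small negative ripple after low-passing the
rectified signal is clipped at zero so "processed EMG" is a nonnegative
activity signal.

A 200 Hz envelope cutoff on 1 kHz data is unusually high for envelope
extraction; it is implemented as specified and config-exposed
(`emg_lowpass_hz`).  Consequently the processed signal retains large
sample-level fluctuation (relative SD ~0.37 for a stationary carrier); all
downstream quantities are window averages (RMS over >= 100 ms), which is
where the envelope information lives.

## 2. Movement events and epochs

Angular acceleration is the double central difference of the filtered angle
(exact for quadratics; one-sided at the two edge samples).  The onset
threshold is `T = mean(|acc|) + k*std(|acc|)` over a baseline window
(default: the first 500 ms of the trial — the task is self-initiated from
quiet stance), `k = 3`, floored at `rel_floor * max(|acc|)`.

The floor matters only in the degenerate noiseless case: there the baseline
statistics vanish to machine precision and the zero-phase filter's tiny
backward smear of the movement would trigger detection a few ms early.  On
noiseless minimum-jerk input the smear crosses 2% of peak acceleration about
4 ms before true onset and 5% exactly at the onset sample; the default
`rel_floor = 0.05` (a conventional percent-of-peak kinematic onset rule)
therefore detects `t0` and `tf` with 0 ms error on clean input, and is
irrelevant on noisy input where `mu + 3*sigma` dominates.

`t0` is the first sample whose following 25 ms stay above threshold; `tf`
is the last sample of the final supra-threshold excursion followed by at
least 200 ms below threshold.  The epochs are half-open windows —
APA `[t0-200, t0+50)`, OPA `[t0+50, tf)`, CPA `[tf, tf+250)` ms — so the
three epochs exactly partition the analysis span with no double-counted
boundary sample.  All window offsets are config-exposed.

## 3. Activity metrics

* **Epoch RMS**: root mean square of processed EMG over the window.
* **Normalized intensity**: `100 * RMS / (0.95 * M)` where `M` is the
  repetition-maximum RMS of that channel.  How `M` was computed is not
  prescribed anywhere; the default is the maximum 100-ms moving-window RMS
  over the whole repetition (`max_rms_mode="moving"`); the maximum of the
  three epoch RMS values is available behind `max_rms_mode="epoch"`.
  Intensity is therefore bounded by 100/0.95 ~ 105.26 %MAX and is invariant
  to any per-channel gain.
* **Latency**: threshold `3*mu + 3*sigma` of the baseline ("pre-activity")
  window `[t0-450, t0-250)` ms, searched over `[t0-200, t0+50]` ms with a
  10-ms sustain requirement; undefined (NaN) if no sustained crossing.  The
  literal threshold reading ("three times the baseline signal plus three
  standard deviations") is the default; `mu + 3*sigma` is available via
  `latency_rule`.  Undefined latencies are excluded from averages and
  counted in the report.
* **R / C indices**: per joint (hip RA/LE, knee RF/BF, ankle TA/GL —
  the only flexor/extensor pairs in the montage; both indices are invariant
  under swapping the pair) from normalized intensities:
  `R = |a - b|`, `C = a + b`.  With nonnegative inputs `0 <= R <= C` always.

## 4. Synergy extraction

For one condition x epoch, the processed EMG samples of all trials are
stacked into an observations x 7 matrix and each muscle column is z-scored
over the pool; PCA is the eigendecomposition of the resulting correlation
matrix.  Correlation (not covariance) PCA is used because channel gains are
arbitrary.  Components are ordered by descending eigenvalue with the sign
convention that the largest-magnitude loading is positive, making outputs
comparable across runs.  `min_components` is the smallest k whose cumulative
variance fraction reaches the threshold (default 0.75).  Reconstruction
residual RMS at rank k pools all matrix entries.

The retained 2-4 PC scores are whitened and rotated by FastICA (log-cosh
negentropy, max 1000 iterations, tolerance 1e-6) with a seeded initial
rotation.  Restart schedule: the symmetric ("parallel") update at the strict
tolerance, then at a 100x relaxed tolerance, then the deflation update —
each with 5 deterministically seeded rotations.  The symmetric fixed point
can cycle between equivalent rotations on weakly non-Gaussian pooled-epoch
data where deflation still converges; the schedule is fully deterministic,
so same seed -> bit-identical unmixing.  If everything fails an error
carrying the iteration budget is raised; for isotropic Gaussian input ICA is
unidentifiable and non-convergence (or an arbitrary rotation) is the
documented outcome.  Independent components are ordered by back-projected
variance and sign-fixed like the PCA loadings.

Pooling unit: one decomposition per condition x epoch across trials.  The
trial-level replication needed by the variance/dimensionality ANOVAs comes
from per-trial, per-epoch PCAs (z-scored within the trial's epoch), written
to `trial_variance.tsv`.

## 5. Statistics

Fixed-effects factorial ANOVAs (type II) on trial-level tables, trials
pooled across participants — matching the original trial-level denominator
degrees of freedom; subjects are not modeled as random effects.  Tukey HSD
for post hocs (familywise alpha 0.05).  Cross-phase correlation: within one
condition, the 7 muscle-level mean intensities of phase A are correlated
with those of phase B (Pearson, n = 7), giving one (r, R^2, p) per condition
and phase pair.  No multiple-testing correction is applied across the
comparison families; the report says so.

## 6. The synthetic world

Each trial (default 4 s at 1 kHz) contains:

* **Kinematics**: a minimum-jerk flexion
  `theta(s) = 90 deg * (10 s^3 - 15 s^4 + 6 s^5)` of 500 ms starting at
  `t0 = 1000 +- 100` ms (uniform jitter; the task is self-initiated), then a
  hold.  Angle noise defaults to zero (the acceptance checks for onset
  detection are defined on noiseless kinematics); `angle_noise_deg` adds
  goniometer-like white noise.
* **EMG**: per muscle, a band-limited Gaussian carrier (white noise
  high-passed at 20 Hz, the acquisition band's lower edge; the upper edge is
  Nyquist) multiplied by a piecewise envelope, plus an independent carrier
  at the noise floor (default: a silent channel reads 1 %MAX).
* **Envelope**: plateaus over the active part of each phase — APA activity
  starts at the muscle's burst onset (latency table + 10 ms jitter), OPA and
  CPA span their windows — joined by 25-ms half-cosine ramps placed inside
  the higher-level segment, so a quiet window never inherits spill-over from
  a loud neighbour.
* **Normalization burst**: a ~170-ms unit-envelope burst 400 ms after
  movement end (during the loaded hold, outside all analysis windows)
  realizes each channel's repetition-maximum RMS.  The trial gain is *not*
  applied to it; intensity is per-channel scale-invariant, so a gain on the
  whole channel would be unrecoverable by construction.
* **Amplitudes**: per trial, each (muscle, phase) amplitude is drawn from a
  Gamma distribution with the published mean and SD (support >= 0 with exact
  mean — a truncated normal would bias the high-SD anticipatory cells by up
  to ~10 %MAX), multiplied by the trial gain, clipped at 105 %MAX.
* **Trial gain**: log-normal with mean exactly 1 and SD `shared_gain_sd`
  (default 0.1), shared by all postural muscles and phases; the gain-induced
  variance is subtracted from the Gamma draw variance so the total per-trial
  SD matches the published table.  `gain_groups` / `gain_per_muscle` allow
  phase-grouped and per-muscle gains for correlation experiments.
* **Latency defaults** (free parameters; the source reports latencies only
  graphically): AD -120, LE -80, BF -70, RF -60, GL -50, RA -30, TA +20 ms.
  Muscles with a large anticipatory amplitude must onset early for the world
  to be self-consistent — the window-average intensity over `[onset, t0+50)`
  cannot exceed ~105 * sqrt(active fraction) without the anticipatory
  envelope itself becoming the repetition maximum.  For the same reason a
  trial whose drawn anticipatory amplitude is too large for its drawn onset
  has the onset advanced (never before the window start); the adjusted onset
  is what lands in the ground truth, mirroring the physiological scaling of
  anticipatory adjustments.

### Calibration

The generator is calibrated in closed form against the pipeline's noise
model, not tuned empirically per dataset.  Two constants are estimated once
per configuration from a fixed-seed simulation of the carrier model and
cached: `rho`, the processed RMS per unit envelope, and `kappa`, the
expected maximum moving-window RMS of the normalization burst in envelope
units.  `kappa` exceeds `sqrt(1 + noise^2)` by ~5% because a maximum over
overlapping windows is an extreme-value statistic; ignoring that bias would
deflate every recovered intensity by the same ~5%.  Envelope plateau levels
then solve `windowed mean square of env^2 + noise^2 =
(0.95 * kappa * a / 100)^2` for programmed amplitude `a`, with a short
fixed-point loop absorbing the ramp geometry.  The white-noise variance gain
of the zero-phase filters is computed from the frequency response
(`sqrt(mean |H|^4)`), so carriers have unit variance by construction rather
than by per-realization normalization.

### What the measurement itself does to the numbers

Two consequences of the published normalization are reproduced, not
suppressed, by the generator:

* **Ceiling compression.**  An epoch whose drawn amplitude approaches ~98
  %MAX becomes its own repetition maximum; its intensity saturates near
  100/0.95 and the rest of the channel deflates slightly.  Cells with high
  mean + SD (e.g. GL online on the elevated platform, 84.9 +- 21.1) are
  recovered ~2-3 %MAX below the programmed mean for this reason.
* **Within-repetition coupling.**  All three phases of a (trial, muscle)
  share the repetition-maximum denominator, whose per-repetition fluctuation
  is ~5-7% (extreme value of window RMS).  Hence (i) recovered intensities
  show a residual cross-phase correlation (~0.4-0.5 at 10% amplitude SD)
  even with the shared gain off — the *programmed* amplitudes are exactly
  uncorrelated then — and (ii) a pooled one-way phase ANOVA on intensity is
  conservative under the null (~2% type-I at nominal 5%), because the
  shared denominator inflates within-group variance symmetrically across
  phases.  Type-I calibration is therefore checked on epoch RMS (the
  response of the study's comparison family on raw activity), which has no
  shared denominator and achieves the nominal rate; the intensity-based
  rate is verified to be conservative, never inflated.

### What a green test establishes

Parameter recovery on 80 trials/condition shows the pipeline is an unbiased
(to within the effects above) estimator of the programmed amplitude
structure, that movement onsets are recovered to ms accuracy on clean
kinematics, and that the programmed orderings (online phase highest for all
postural muscles, anticipatory TA at the noise floor) survive the full
measurement chain with the published thresholds and window constants.  The
generator does not emulate electromechanical delay physiology, electrode
crosstalk, fatigue drift, non-stationary baselines, or inter-subject
amplitude idiosyncrasies (subject ID only partitions the seed stream), so
green tests say nothing about robustness to those; nor can any synthetic
world validate the original study's empirical F or R^2 values, which came
from unreleased human recordings.

## 7. Reproducibility

Every random quantity derives from a single seed through per-trial
`SeedSequence([seed, condition, subject, rep])` streams, so any subset of
trials regenerates identically and datasets are pure functions of
(config, seed).  The pipeline manifest records the config hash, seed,
library versions and SHA-256 of every output; identical seeds yield
byte-identical outputs.
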