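# posturemg

Analysis of postural-adjustment surface EMG around a fast bilateral arm
raise, together with a calibrated synthetic-trial generator so that every
stage of the pipeline can be verified against known ground truth.

## The problem

When a standing person raises both arms as fast as possible, postural
muscles of the trunk and legs act in three phases around the focal movement:
an **anticipatory** adjustment (APA) that precedes movement onset, **online**
adjustments (OPA) during the movement itself, and **compensatory**
adjustments (CPA) after it ends.  Experiments of this kind record the
shoulder angle (electrogoniometer) plus seven surface EMG channels at 1 kHz
— anterior deltoid (AD, the focal mover), lumbar extensor (LE), rectus
abdominis (RA), rectus femoris (RF), biceps femoris (BF), tibialis anterior
(TA) and gastrocnemius lateralis (GL) — under a 2x2 design: support height
(floor vs a 1-m elevated platform, a purely perceived postural threat) and
vision (eyes open vs closed).

`posturemg` implements the full analysis chain:

1. **preprocess** — EMG: mean removal, full-wave rectification, zero-phase
   4th-order Butterworth low-pass at 200 Hz.  Angle: zero-phase 4th-order
   low-pass at 20 Hz.
2. **segmentation** — movement onset `t0` and end `tf` from the onset of the
   angular acceleration (double derivative of the angle), then the half-open
   epochs APA = [t0-200, t0+50), OPA = [t0+50, tf), CPA = [tf, tf+250) ms.
3. **activity metrics** — per trial x muscle x phase: epoch RMS; normalized
   EMG intensity `100 * RMS / (0.95 * max RMS of the repetition)` in
   %MAXIMUM; muscle onset latency (first crossing of `3*mu + 3*sigma` of the
   pre-activity baseline, searched over the anticipatory span); and the
   joint-level indices for hip (RA/LE), knee (RF/BF) and ankle (TA/GL):

   - reciprocal inhibition `R = |I_agonist - I_antagonist|`
   - coactivation `C = I_agonist + I_antagonist`
4. **synergy** — trials pooled per condition x epoch into an observations x 7
   matrix (z-scored), PCA on the correlation matrix (variance fractions, the
   minimum number of components reaching 75% of total variance, rank-k
   reconstruction residual RMS), then FastICA (fixed-point log-cosh
   negentropy, seeded) on the retained components to extract statistically
   independent muscle synergies.
5. **stats** — factorial trial-level ANOVAs with Tukey HSD post hocs for the
   study's comparison families (intensity/RMS, latency, R/C indices, PC
   variance fractions, minimum component count), and the cross-phase
   correlation of condition-mean muscle activities (Pearson r across the 7
   muscles per condition and phase pair).

Because the original recordings are not deposited, the package ships a
**synthetic-data module**: minimum-jerk shoulder kinematics, EMG channels
built as band-limited (20-500 Hz) Gaussian carriers amplitude-modulated by
phase-locked envelopes, per-trial amplitudes drawn around the published
condition x phase x muscle means/SDs, per-muscle burst onsets, and a
trial-level shared gain that induces cross-phase amplitude correlations.
The envelopes are calibrated against the pipeline's own noise model so the
expected recovered intensity equals the programmed amplitude (see
`docs/methods.md`).

## Worked example

```python
from posturemg.pipeline import PipelineConfig, run_pipeline
from posturemg.simulate import small_config

config = PipelineConfig(generator=small_config(n_subjects=2, n_reps=3), seed=7)
manifest = run_pipeline(config, "demo_out")
```

or, from the shell, `posturemg run --seed 7 --out demo_out` (the default
configuration generates the full 8 subjects x 10 repetitions x 4 conditions
= 320 trials).  The run writes `activity.tsv`, `indices.tsv`,
`synergies.tsv`, `variance.tsv`, per-trial event JSONs, a ground-truth
table, `stats_report.json` / `report.md`, and a manifest with the seed and
output hashes.  Averaging `activity.tsv` over the 24-trial demo gives:

```
phase    APA   CPA   OPA
muscle
AD      52.3  53.6  66.9
BF      56.1  60.1  68.6
GL      25.5  47.2  78.7
LE      33.7  56.1  74.1
RA      16.8  67.4  75.2
RF      47.8  55.3  67.6
TA       2.7  47.6  77.3
```

Intensities are in %MAXIMUM.  The programmed structure is visible: every
muscle is most active during the online phase; TA is nearly silent
anticipatorily (near the 1% noise floor) yet among the strongest online;
the focal AD is the only muscle already strongly active before onset.  The
statistics report for the same run shows the phase effect
(`F(2, 493) = 223.2, p = 9.4e-70`) and the cross-phase correlation table,
e.g. on the floor with eyes open `R^2(APA, OPA) = 0.58 (p = 0.046)` against
`R^2(APA, CPA) = 0.04` — the anticipatory/online coupling that emerges from
the amplitude table alone.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a synthetic dataset from scratch and runs the complete pipeline
(preprocessing, segmentation, metrics, synergies, statistics) under the
given seed, writing the JSON results file. All inputs are generated at run
time; nothing is read from outside the repository.

## Layout

```
src/posturemg/
  io.py            trial container, TSV + JSON sidecar I/O
  preprocess.py    zero-phase Butterworth conditioning
  segmentation.py  acceleration-onset events, APA/OPA/CPA windows
  metrics.py       RMS, normalized intensity, latency, R/C indices
  simulate.py      calibrated synthetic-trial generator
  synergy.py       correlation PCA + FastICA synergies
  stats.py         ANOVA / Tukey HSD / cross-phase correlations
  pipeline.py      orchestration, config, manifest
  cli.py           `posturemg` subcommands
docs/methods.md    model, calibration and numerical choices
```
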