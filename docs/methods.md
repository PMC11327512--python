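# Methods

## Problem and approach

Aspiration — food or liquid entering the airway below the vocal folds during
swallowing — is normally diagnosed by videofluoroscopy (VFSS) and graded on
the Penetration-Aspiration Scale (PAS), which requires imaging equipment and
specialist interpretation. A complementary screening signal is the voice
itself: residue on or near the vocal folds after swallowing changes
phonation (higher jitter and shimmer, lower harmonics-to-noise ratio), so
the *change* between a sustained "ah" vowel recorded immediately before and
immediately after swallowing carries information about aspiration that
either recording alone does not.

`swallownet` implements this paired change-detection pipeline end to end:

1. **Standardization.** Heterogeneous recordings (wav/mp3/m4a, mono or
   stereo, arbitrary rate) are endpoint-trimmed, stereo-split, resampled,
   and cut into exactly 2-s mono segments. Segmentation uses consecutive
   non-overlapping windows from sample 0, discarding the sub-2-s tail: the
   simplest reproducible rule, and overlap would multiply correlated
   samples within a subject.
2. **Pairing and folds.** Within each subject (and substance session, when
   that metadata exists), every pre-swallow segment is paired with every
   post-swallow segment. Folds for 10-fold cross-validation are assigned at
   the *subject* level, label-stratified, so no individual contributes to
   both a training and a test split. Training splits may be balanced by
   random oversampling of minority-label pairs; test splits are never
   touched.
3. **Front end.** Each 2-s segment becomes a 128-band log-power mel
   spectrogram (32 kHz, 20-ms Hann window, 10-ms hop, 640-point FFT) of
   shape (128, 201).
4. **Model.** A width-scalable inverted-residual convolutional encoder is
   applied to the pre and post spectrograms (shared weights by default),
   the feature maps are concatenated along channels, a decoder expands the
   concatenated channels 6x then 2x (12x total) with 1x1 convolutions, and
   a fully convolutional head (global average pooling + 1x1 convolution)
   emits one logit. Sigmoid of the logit is the aspiration probability.
5. **Training and evaluation.** Adam, binary cross-entropy on logits, no
   weight decay, and a piecewise schedule (constant, then linear decay over
   a 5-epoch window to 1% of the initial rate). Metrics per fold: AUC,
   accuracy, sensitivity, specificity, F1, PPV, NPV, and BCE loss, with the
   conservative decision rule that a sample is called normal only when
   P(normal) strictly exceeds 0.5. Fold summaries report mean, unclipped
   95% t-intervals, and max.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| segment length | 2 s | the unit of analysis; 64,000 samples at 32 kHz |
| mel bands / window / hop / FFT | 128 / 640 / 320 / 640 | front-end operating point; yields (128, 201) per segment |
| pre-emphasis | 0.97 | conventional first-order high-pass coefficient |
| width multiplier | 0.25 | channel scale; 2.0 reproduces the memory-bound clinical configuration |
| decoder expansions | (6, 2) | successive channel expansion after concatenation |
| batch size / epochs | 16 / 15 (desk) | clinical-scale grid is 16 or 32 / 150 |
| lr0 | 1e-3 (desk) | clinical-scale values are 5e-5 / 3e-5, with decay from epoch 100 to 105 |
| decision threshold | 0.5 | on P(normal), strict inequality |
| folds | 10 | subject-grouped, label-stratified |

Desk-scale defaults (width 0.25, lr 1e-3, 15 epochs) exist because the
package trains a randomly initialized small network on synthetic cohorts;
the clinical configuration (width 2.0, lr 3e-5/5e-5, 150 epochs) is
available through the same config objects.

Front-end details the operating point does not pin down were fixed once:
Hann window with centered reflect-padded framing, power (squared-magnitude)
spectra, Slaney mel band spacing and area normalization over 0..sr/2
(HTK spacing available as a flag), and natural-log compression floored at
1e-10. These follow common audio-CNN front-end practice and are frozen in
`MelConfig` so shapes and values are bit-stable.

## The synthetic cohort generator

No public recordings exist for this task, so the package ships a
source-filter vowel generator used by every end-to-end test. Each subject
is a parameter set (f0 from a sex-specific range, baseline jitter ~0.5%,
shimmer ~3%, HNR ~25 dB); each recording is a glottal pulse train with
per-cycle period jitter and amplitude shimmer, -12 dB/oct source tilt,
three /a/ formant resonators (800/1200/2500 Hz), and white noise scaled to
the HNR target, peak-normalized to 0.9. The class signal is injected only
as a *pre-to-post change*: aspiration-group post recordings receive
additive jitter/shimmer increments and an HNR decrement (`post_delta`,
default +2% jitter, +6% shimmer, -10 dB HNR).

Two design choices follow from small-cohort statistics and are the
generator's most important properties:

- **Matched baselines.** Baseline parameter sets are drawn once per (sex,
  slot) and shared between the normal and aspiration groups. With
  independent draws, a 40-subject cohort shows chance baseline-vs-label
  correlations of roughly 0.09 AUC standard deviation, which a
  high-capacity network reproduces in held-out subjects of the same cohort
  — not leakage, but indistinguishable from it at this scale. Matching
  removes every baseline confound by construction, leaving the post-swallow
  change as the only systematic group difference.
- **Twin co-folding.** Matched pairs are kept in the same
  cross-validation fold (`twin_key`, `assign_folds(match_keys=...)`), the
  standard practice for matched designs: otherwise a test subject's
  opposite-label twin is in training, and the model scores the test subject
  like its twin, biasing the null well below chance.

Cohort size defaults to 10 subjects per (group x sex) cell — 40 subjects,
160 pairs — the smallest cohort at which every fold's test split contains
two subjects per class, so that a fold's AUC is not a single
between-subject comparison and the chance band of the 10-fold mean
(standard deviation about 0.1) is informative.

What the generator does *not* emulate: room acoustics and device coloring,
non-stationarity within a phonation (onset/offset, vibrato, voice breaks),
wet phonation or gurgle, inter-session variability, or any relation between
comorbidities and voice. Passing tests therefore demonstrate that the
pipeline is leak-free, reproducible, and able to learn a pre/post acoustic
change of plausible magnitude — not that the model screens real patients.

## Integrity checks

Three full 10-fold cross-validation runs over increasing effect size anchor
the test suite and the acceptance script:

- `post_delta = 0` (null): mean AUC must sit at 0.5 +/- 0.15. This is the
  pipeline's leakage detector — any subject overlap, oversampling of test
  splits, or fold contamination shows up here first.
- the default delta (separable): mean AUC must reach at least 0.85 at desk
  scale (width 0.25, 15 epochs).
- monotonicity: mean AUC must be non-decreasing from null through a small
  delta (+0.5% jitter, +1.5% shimmer, -2.5 dB HNR) to the default, within
  one fold-standard-deviation.

Problem sizes were chosen so the whole suite trains thirty 84k-parameter
models: 40 subjects per cohort, 160 pairs, 15 epochs, batch 16.

## Numerical choices and degenerate inputs

- The layer engine computes in float32 with float64 loss/gradient scalars;
  convolutions run as im2col matmuls with a 1x1 fast path, and the shared
  encoder processes the batch-stacked [pre; post] tensor so each layer
  instance is traversed exactly once per step.
- Batch-norm uses batch statistics in training and running statistics
  (momentum 0.1) at evaluation; evaluation-mode forward passes are
  deterministic.
- Metrics with zero denominators (e.g. PPV when nothing is called
  aspiration) are reported as NaN, never as 0, and are excluded from fold
  summaries; AUC requires both classes and raises otherwise.
- 95% confidence intervals over folds use the t distribution and are not
  clipped to [0, 100]: near-ceiling metrics legitimately produce upper
  bounds above 100%.
- Yates continuity correction is applied to 2x2 contingency tables only;
  wider tables use the plain Pearson statistic. This pairing reproduces the
  reference cohort statistics exactly and is recorded as a derived
  assumption.
- Empty waveforms, single-label splits, zero-norm spectrograms, sub-2-s
  inference clips, and fold/split misses all raise explicit errors rather
  than propagating NaN.
- mp3 transcoding requires an external codec (ffmpeg or lame); without one
  the operation raises an explicit environment error and the dataset store
  uses RIFF/WAV byte payloads (the codec is recorded in the store's
  attributes, so mp3-encoded stores read back transparently where a codec
  exists).

## Known limitations

- The encoder follows the inverted-residual design at reduced depth
  (stem + three stride-2 blocks with expansion ratios 1/4/4); it does not
  claim per-block equivalence with any published audio-tagging network.
- Whether the 12x decoder expansion multiplies the concatenated channels or
  the per-branch channels is ambiguous in the source description; this
  implementation expands the concatenated budget and records the
  interpretation in every checkpoint.
- Augmentation (the 2-of-7 waveform composition) is off by default for the
  synthetic integrity runs: heavy waveform noise would confound the
  injected pre/post change at desk scale. The train-only contract is
  implemented and tested regardless.
- Inference on recordings longer than 2 s uses the first segment by
  default; `--aggregate mean` averages probabilities over all full
  segments. Multi-segment aggregation at inference is otherwise
  unspecified.
- Training evaluates the final-epoch model; no best-epoch checkpoint
  selection is performed, and the full per-epoch history is recorded.
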