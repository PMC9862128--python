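# Methods

## Problem and pipeline

`ecgid` implements a non-fiducial ECG biometric identification pipeline for
single-lead recordings. No beat detection or landmark extraction is
performed anywhere; instead each fixed-length window of the cleaned signal
is mapped to a Gramian Angular Summation Field (GASF) image and a
convolutional classifier assigns the image to one of the N enrolled users
(closed-set identification).

Stages:

1. **Cleaning** — subtract the mean (DC), then band-pass 0.67–45 Hz with an
   order-4 Butterworth applied forward-backward (`scipy.signal.sosfiltfilt`).
   The high-pass edge removes baseline wander (respiratory drift, < 0.7 Hz);
   the low-pass edge removes 50/60 Hz mains interference. Zero-phase
   filtering is used so the PQRST morphology, which carries the identity
   signal, is not skewed in time. The published account of this kind of
   system prints an upper cutoff that would sit below its lower cutoff;
   0.45 is read here as 45 Hz, which matches the filter's stated purpose,
   and both edges are configuration values (`PreprocessConfig`).
2. **Windowing** — non-overlapping windows of W = 5 s (several heartbeats;
   a plausible authentication interval). A trailing remainder shorter than
   W is discarded; a recording shorter than W yields zero windows and a
   warning. A fractional `overlap` is available but defaults to 0.
3. **GASF encoding** — the window is reduced to m samples by Piecewise
   Aggregate Approximation (frame means; fractional frames are handled by
   exact weighted averaging), min-max rescaled to [-1, 1]

       x~_i = ((x_i - max X) + (x_i - min X)) / (max X - min X),

   mapped to angles phi_i = arccos(x~_i), and encoded as the matrix
   G_ij = cos(phi_i + phi_j). G is symmetric with entries in [-1, 1] and
   diagonal G_ii = 2 x~_i^2 - 1. The encoding is invariant to positive
   affine transforms of the window's amplitude, so no amplitude calibration
   is required of the input.
4. **Classification** — a VGG-style network on the m x m images (below).
5. **Metrics** — accuracy, confusion matrix, FRR, FAR and K = FRR/FAR.

## Invertibility and its limit

The rescaled series is recoverable from the image diagonal. In unit-mode
rescaling ([0, 1]) the recovery x~_i = sqrt((G_ii + 1)/2) is exact and
single-valued. Under the symmetric [-1, 1] rescaling the diagonal gives
only |x~_i|, and the full matrix is invariant under global negation of the
series (phi -> pi - phi leaves every cos(phi_i + phi_j) unchanged), so signs
are recoverable only relative to a reference element. `gasf()` therefore
records the index of the window maximum (rescaled value +1) in the image's
provenance; `recover_series()` resolves every sign against it through the
off-diagonal identity G[i, ref] = x~_i when x~_ref = 1. For hand-built
images without provenance the largest-magnitude element at the smallest
index is assumed positive — a convention, documented as such. Round trips
through `rescale -> gasf -> recover_series` reproduce the rescaled series to
1e-9 in both modes.

## The classifier

Layer sequence (fixed; sizes configurable through `ModelConfig`):

    input (m x m, 1 or 3 channels)
    conv3x3(s1) ReLU, conv3x3(s1) ReLU, maxpool2      } two VGG-style
    conv3x3(s2) ReLU, conv3x3(s2) ReLU, maxpool2      } stem blocks
    5 x [conv3x3(core) ReLU]                            tuned core
    maxpool2, global-average-pool, dropout(p_core)
    dense(d) ReLU, dropout(p_head), dense(N) -> softmax

Two profiles:

* **full** — stem 64/128 filters, core 5 x 512, dense 256, dropout
  0.25/0.10, Adam at 1e-5, 128 x 128 inputs replicated to 3 channels.
  This is the published configuration's shape (millions of trainable
  parameters; the exact count is exposed via `Network.parameter_count()`).
  Pretrained stem initialisation from public image-classification weights
  is accepted as a flag but no weight file is bundled; requesting it raises,
  and seeded He initialisation is the supported path.
* **desk** — the same shape shrunk to train end-to-end on one CPU in
  minutes: stem 8/16, core 5 x 64, dense 128, single channel, Adam at 1e-3,
  batch 8, 60 epochs. Dropout is set to 0 in this profile: at this scale
  it slowed optimisation badly while the augmentation below regularises
  more effectively. Both dropout layers remain in the graph (p = 0).

The network engine is a self-contained float32 numpy implementation
(channels-last convolutions as nine offset matmuls, max/global-average
pooling, inverted dropout, dense layers, softmax cross-entropy, Adam with
bias correction). Gradients were verified against central finite
differences. Training is bit-reproducible given the config seed (data
order, initialisation, dropout and augmentation all derive from it).

Two training-time devices matter at desk scale:

* **Per-pixel input standardisation** (`standardize_inputs`) — images are
  z-scored with train-set statistics (stored on the trained model and
  re-applied at prediction). Without it, optimisation on small cohorts is
  slow and seed-sensitive.
* **Circular time-shift augmentation** (`augment_time_shift`) — a circular
  shift of the time window is exactly a joint row/column roll of its
  Gramian, so each training image is presented with a random diagonal roll.
  This teaches the translation invariance that beat-phase differences
  between windows demand, and is the single largest contributor to
  generalisation at 19 training windows per subject.

Early stopping monitors validation loss with `early_stop_patience` and
restores the best epoch's weights. The desk profile sets patience equal to
the epoch budget: with only ~20 validation images the loss is too noisy to
arrest training safely, so the profile keeps best-epoch checkpointing but
never stops early.

## Identification metrics

With rows = true user and columns = predicted user:

* accuracy = trace / total;
* FRR = fraction of genuine probes not credited to their identity
  (= 1 - accuracy without a rejection threshold);
* FAR = macro average over users i of (probes of other users labelled i) /
  (probes of other users);
* K = FRR / FAR, reported as undefined (None) when FAR = 0.

For balanced probe counts and argmax decisions, FAR = FRR/(C-1) identically,
hence K = C-1 (9 for 10 enrolled users) whenever at least one probe is
misclassified. An optional threshold tau rejects probes whose top softmax
probability falls below it; rejections count as false rejections and are
excluded from false-accept counts, making FRR non-decreasing and FAR
non-increasing in tau.

## Synthetic cohorts

Each synthetic identity is a sum-of-Gaussians PQRST template on a beat
phase axis theta in [-pi, pi): five waves with per-subject angles,
amplitudes and widths drawn from a population whose means are the standard
dynamical-ECG-model values (theta = (-1.22, -0.26, 0, 0.26, 1.75) rad,
a = (0.12, -0.5, 1.5, -0.75, 0.35), b = (0.25, 0.10, 0.10, 0.10, 0.40) rad,
65 bpm). Between-subject standard deviations default to 15% of each mean
and per-beat within-subject jitter to 3%, so between-subject variation
dominates within-subject variation; this identifiability condition is
enforced at configuration time. The R-wave angle is the phase anchor
(mean 0), so its between- and within-subject sd are both 0 by construction
and it deliberately carries no identity.

Rhythm: per-beat heart rates are drawn Normal(HR, hr_sd) (hr_sd ~ 3 bpm,
the scale of real resting beat-to-beat variability), each beat spanning one
RR interval linearly in phase — no intra-beat warping, since morphology
rather than rhythm dynamics carries identity here. Subject mean HR is
truncated to 50-100 bpm.

Nuisance components, amplitudes in units of the template (R wave = 1.5):
sinusoidal baseline wander at 0.3 Hz (amplitude 0.2), 50 Hz mains
(amplitude 0.05), white sensor noise (sd 0.03). Five activity profiles
scale heart rate, broadband noise and wander monotonically: resting
(1.0/1.0/1.0), math (1.15/1.2/1.0), walking (1.5/2.0/1.5), running
(2.0/3.5/2.0), handbike (1.6/3.0/1.8) — emulating progressively demanding
acquisition conditions. Activity-scaled rates outside 30-220 bpm are
rejected as non-physical.

Determinism: per-subject random streams are spawned from the cohort seed
keyed by subject (and activity) index, so any subject's data is independent
of generation order and bit-reproducible.

What the generator does **not** emulate: ectopy and arrhythmia, respiratory
sinus arrhythmia, electrode motion artefacts and dropout, intra-beat
morphology dynamics (rate-dependent QT), or the true inter-subject
variability of any real cohort. Passing results on these cohorts therefore
demonstrate that the pipeline extracts a morphology/rhythm identity signal
under realistic noise — not that any particular accuracy transfers to real
recordings.

## Reference experiments and problem sizes

The desk-scale reference experiment (`ecgid.experiments`) uses 10 subjects,
120 s per activity at 128 Hz, 5 s windows (24 per subject per activity),
PAA to 64 (so 64 x 64 images), a stratified 80/10/10 split, and the desk
profile. These sizes were chosen so a complete run — synthesis through
evaluation — takes about 1.5 CPU-minutes (resting) to 4 CPU-minutes
(four activities), keeping the whole suite and the reproduction script in
the minutes range. Typical resting test accuracy across seeds is
0.75-0.95 with K = 9; mixing in math/walking/running windows costs a few
points. The mixed-activity run trains 40 epochs (four times the data per
epoch makes the budget equivalent).

## Numerical choices

* Rescaling clips values to the target interval after the affine map, so
  endpoints are exact; constant windows raise a degenerate-input error.
* `to_polar` clamps rescaled values within 1e-12 of the interval and
  rejects larger excursions.
* PAA preserves the window mean exactly when the target size divides the
  length, and to weighted-average precision otherwise.
* Argmax ties in prediction resolve to the lowest class index.
* Stratified splits keep at least one image per class in every non-empty
  part and reproduce proportions to within one image per class.
* GAF containers store float64 and round-trip bit-identically.

## Known limitations

* The full VGG19-sized profile is provided and buildable but impractical to
  train in this pure-numpy engine; the desk profile is the supported
  training path.
* Closed-set only: no open-set rejection of unenrolled impostors, no 1:1
  verification ROC/EER analysis, no cross-session or template-aging
  evaluation.
* Single-lead only; no multi-lead fusion, annotations, or clinical header
  metadata.
* The symmetric-mode inverse GAF is canonical only through the stored
  reference index (see above).
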