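# Methods

## Problem

An observer's scanpath — the ordered sequence of fixations their gaze makes
on a stimulus — carries a signature of who is looking, not only of what is
looked at. In a museum setting, adults viewing paintings tend to hold their
gaze near the center of the composition, while children sweep repeatedly
between the left and right halves of the image. `scanpix` turns that
behavioural difference into a supervised image-classification problem: each
scanpath is rendered as a small set of rasters and a convolutional network
learns to label the viewer class (adult vs child) from them.

## The view transformation

A fixation table supplies, per fixation, the screen position in pixels
(origin at the top-left corner of a 1920×1080 display, x rightward,
y downward) and the duration in milliseconds. For fixation *i* at point
*p_i* we compute:

- **arrival angle** θ_i = atan2(y_i − y_{i−1}, x_i − x_{i−1}), the direction
  of the saccade that reached *p_i*. The two-argument arctangent is used
  because the arctangent of the slope alone cannot distinguish a movement
  from its reversal; the value is shifted by +π so every deposited angle is
  positive. Coincident consecutive fixations get θ = 0 by convention.
- **lag distances** r−k = ‖p_i − p_{i−k}‖ for k ∈ {1, 2, 3, 5, 10}: how far
  the gaze has travelled over the last k steps. A point is the endpoint of
  many possible trajectories; the set of lag radii summarizes the recent
  trajectory at several horizons.
- **lead time** L_n(i) = Σ duration over the min(n, i) fixations preceding
  *i*, for n ∈ {3, 10}: how long the gaze dwelt in the recent past.
- the **fixation duration** itself.

Whenever the required predecessors do not exist (the first fixation, or
i < k), the value is 0 — the no-information raster value.

These nine quantities are grouped into three 3-channel images:

| image | channel 0 | channel 1 | channel 2 |
|-------|-----------|-----------|-----------|
| PI (punctual)  | θ (shifted) | r−1  | duration |
| MI (mean)      | r−2         | r−3  | lead time, n = 3 |
| LI (long)      | r−5         | r−10 | lead time, n = 10 |

Each fixation deposits its values at the grid cell
(⌊x·W_g/W_s⌋, ⌊y·H_g/H_s⌋) of a W_g×H_g raster (default 224×224, the input
resolution of common CNN backbones). Deposition is punctual — values are
written directly at the scaled coordinate, not drawn at screen resolution
and resampled, which would smear single-pixel deposits across cells. When
several fixations land in one cell the channel-wise **maximum** is kept
(default; `last` and `sum` are configurable) — max is order-independent and
preserves the strongest signal.

Finally each channel is scaled independently:
NData = Data · 255 / MaxData, where MaxData is that channel's maximum in
that image, rounded to the nearest integer with halves away from zero. A
channel containing any positive deposit therefore attains exactly 255
somewhere; an all-zero channel stays zero. The θ channel can instead be
normalized by the fixed range 2π (`theta_fixed_range`), which makes angle
intensities comparable across images at the cost of no longer saturating
the 8-bit range; the per-image maximum is the default.

## Synthetic cohorts

The simulator generates labeled surrogate cohorts with the coarse
statistical structure of free-viewing museum data:

- **Durations**: log-normal with mean 300 ms (the textbook average fixation
  pause) and coefficient of variation 0.30 — a realistic right-skewed,
  strictly positive spread.
- **Viewing budget**: fixations accumulate until the next one would exceed
  15 s per stimulus; the overshooting fixation is discarded, so totals are
  capped at the budget and fall short of it by about half a mean fixation
  in expectation (≈1%).
- **Adult profile**: positions drawn from an isotropic Gaussian at screen
  center with std 0.08 of the screen width.
- **Child profile**: the horizontal mean follows a triangular wave sweeping
  ±0.30 of the screen width around the center with a period of 16
  fixations, with Gaussian scatter of 0.12 of the width (horizontal) and of
  the height (vertical) around the drifting mean.
- Both profiles add a small saccade jitter (std 0.02 of the width);
  out-of-bounds proposals are rejection-sampled rather than clamped, which
  would pile artificial density onto the screen edges.

Five stimuli per subject and an 18-adult / 16-child roster are the default
cohort, giving 170 scanpaths and 510 encoded images. Per-subject random
streams are spawned from the master seed, so cohorts are reproducible both
as a whole and per subject.

What the simulator does *not* model: stimulus content (no saliency-driven
gaze), saccade main-sequence kinematics, tracker noise and drop-outs,
inter-subject variability of the profile parameters, or any overlap
between the two classes' spatial strategies beyond their shared center.
Passing tests on surrogate cohorts therefore demonstrate that the encoding
preserves class-discriminative spatial/temporal structure and that the
pipeline is correct and reproducible — not that real adults and children
are this separable. The gap between the two profiles' dispersions is the
explicit knob for downstream difficulty.

## Classifier

The three rasters of one scanpath enter the labeled dataset as three
independent samples sharing the scanpath's label. The 80/20 train/test
split is **stratified and group-aware**: splitting is done over
(subject, stimulus) groups within each class, so the PI/MI/LI siblings of
one scanpath never straddle the split — otherwise near-duplicate images
leak across partitions and inflate accuracy. Per-class train counts are
round(0.8 · groups), e.g. 72 + 64 groups → 408 train / 102 test images for
the default cohort.

The trainable backbone, `small_cnn`, is a compact network trained from
scratch (the published large ImageNet-pretrained architectures are
recognized names, but their weights are not distributed with this
package):

    input (3, 224, 224) in [0, 1]
    → 4×4 average pool            # sparse rasters carry coarse layout
    → conv 5×5, 8 ch, ReLU, 2×2 max pool
    → conv 3×3, 16 ch, ReLU, 2×2 max pool
    → flatten → dense 32, ReLU → dense 2

Inputs are scaled to [0, 1] without centering so the structural zero
background stays exactly zero. Training minimizes 2-class softmax
cross-entropy with SGD. `TrainConfig` defaults (100 epochs, learning rate
1e-4) mirror the fine-tuning protocol appropriate for large pretrained
networks; for the from-scratch compact net the pipeline uses
`DESK_TRAIN_CONFIG` — 15 epochs, learning rate 0.01, momentum 0.9, batch
size 16 — a standard setting for a small randomly initialized CNN, at
which the loss plateaus within about six epochs on the default cohort.
Weight initialization is He-normal; shuffling, initialization and the
simulator all derive from explicit seeds, so training is bit-reproducible
(the `deterministic_mode` flag is kept in the config for interface
stability; the numpy implementation is deterministic under a seed either
way).

Evaluation accumulates argmax confusion counts and reports per-class
precision, recall and F1, their macro (arithmetic) means, and accuracy.
Ratios with a zero denominator are reported as 0 and flagged in the
report's `undefined` list. Reported tables round to 2 decimals (3 for
macro means).

## Numerical and design choices

- Rounding of normalized intensities: nearest integer, halves away from
  zero (fixed for reproducibility; the choice only matters for exact ties).
- Out-of-bounds or non-positive-duration fixations are dropped with a
  logged reason, never clamped.
- The fixation CSV dialect is configurable (column-name map, delimiter);
  with no stimulus column, one file is one stimulus identified by the file
  stem.
- The pipeline fans one master seed into per-stage sub-seeds (simulation,
  split, training) recorded in the run manifest; re-running with an
  identical configuration skips stages whose config hash matches and whose
  outputs exist.
- Problem sizes used by the shipped checks: the encoder oracle comparison
  runs 1000 random scanpaths of up to 50 fixations; simulator calibration
  uses 1000 duration draws and 100 trials; classification checks train on
  the default 18+16-subject cohort for 15 epochs on three seeds.

## Known limitations

- Only the from-scratch compact backbone is trainable; there is no GPU
  path and no pretrained-weight loading.
- The encoder assumes fixations are already detected; raw gaze samples and
  proprietary binary tracker formats are out of scope.
- Surrogate separability is by construction; accuracy numbers on synthetic
  cohorts do not transfer to recorded data.
- The per-image channel normalization discards absolute scale: a short,
  tight scanpath and a long, sprawling one can produce similar intensity
  ranges, with only relative structure distinguishing them.
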