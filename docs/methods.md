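# Methods

This note records the model, its tunable parameters, the numerical
choices behind them, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Background model

A camera-trap burst is a short sequence (typically 10 frames, sometimes
3) taken from a fixed camera over seconds. The scene is static except
for the triggering object and nuisance motion (wind-blown vegetation,
drifting sunspots). The detector treats the image as a 32 × 23 grid of
736 blocks at a 512 × 368 working resolution — 16 × 16 px per block —
and compares co-located blocks across frames through per-block feature
histograms rather than pixels, which buys robustness to exposure
flicker and sensor noise at the cost of block-level localization.

The working size is the smallest landscape resolution at which the
32 × 23 grid tiles exactly with square 16-px blocks; higher-resolution
input is bilinearly resampled (luma only) and boxes are mapped back to
original coordinates rounding outward so an object is never truncated.

**Features.** The default descriptor is a single 9-bin unsigned
gradient-orientation histogram per block, magnitude-weighted, votes
linearly interpolated between the two nearest bins, L1-normalized.
Soft binning matters: with hard binning, an orientation sitting at a
bin edge flips wholesale under infinitesimal noise, and that flip noise
— not gradient magnitude noise — dominated frame-to-frame histogram
jitter in calibration runs. A constant block has no gradient and keeps
an all-zero histogram. Intensity (32 bins), LBP (256 raw 8-neighbor
codes) and GLCM (contrast, shifted correlation, energy, homogeneity at
offset (1,0), L1-normalized like the histograms) are available through
the same interface; the orientation histogram was kept as the default
because it is invariant to uniform brightness change, which exposure
differences between frames otherwise convert into spurious foreground.

**Background selection (MFD).** For each block position, each frame's
score is its L1 distance to the nearest other co-located block; the
frame with the smallest score is the background exemplar and that
smallest distance is the minimum feature distance (MFD). Ties break to
the lowest frame index everywhere, which makes results independent of
frame ordering up to the same permutation. The composite background is
kept per block at the histogram level (the exemplar's histogram), not
as a synthesized image — nothing downstream needs background pixels.

**Foreground threshold.** Block (f, b) is foreground iff
d(h_f(b), h_bg(b)) > max(α · MFD(b), τ_min), α = 2.0, τ_min = 0.25.
The two terms cover different regimes. α · MFD adapts to scenes whose
blocks move constantly (swaying canopy): there the MFD itself is large
and only stronger departures count. τ_min covers static textured
blocks, where the MFD — a minimum over a handful of pairwise distances
— systematically underestimates the typical jitter of its own
distribution. Calibration on static synthetic scenes (σ = 2 sensor
noise, JPEG quality 95) put the jitter of noise-only distances at
median ≈ 0.07 with a tail to ≈ 0.18, while blocks genuinely
re-textured by an object sit at 0.7–1.7 (L1 on unit-sum histograms is
bounded by 2). τ_min = 0.25 clears the noise tail with ~40% margin and
keeps ~3× margin to object signal. Raising α never increases the
foreground set (monotonicity is tested). α ≤ 1 is allowed but warned
about: it reduces the rule to "any distance above the MFD", which
flags essentially everything in a static scene.

**3-frame variant.** For each frame the same rule is applied within
the window of the nearest three frames (clamped at sequence ends).
With fewer background witnesses per block it is noticeably weaker on
fast-moving objects than the composite method and exists for cameras
that record 3-frame bursts; sequences shorter than 3 frames fall back
to the composite method with a log message.

## Region proposals and SHL

Foreground blocks are connected with 8-connectivity; components smaller
than `min_blocks` = 2 are dropped, which suppresses single-block
flicker. The bounding box is the tight union of member blocks mapped to
original coordinates.

Each proposal's patch is screened by the Shrinked Histogram Length:
the count of 8-bit intensity levels whose relative frequency exceeds
`th_hs`. Low-texture intensity artifacts — dark corners beyond flash
range, saturated sunspots, flat gray flash regions — concentrate their
mass on a handful of levels and score a small SHL, while animals and
people span many levels. Defaults `th_hs` = 0.01 and `shl_min` = 12
were chosen on the synthetic fixtures (saturated sunspot patches score
≤ 9, objects ≥ 19 with a wide gap); both are exposed because the right
cutoff depends on patch size and sensor. SHL is invariant to pixel
permutation, non-increasing in `th_hs`, and bounded by min(256, w·h).

## Patch classifier

Candidate patches are padded to a square with edge replication
(aspect-preserving — no anisotropic stretch) and resized to
96 × 96 × 3. The classifier is a five-conv-stage CNN in the reduced
AlexNet-96 mold: per-layer filter counts [16, 32, 64, 64, 32]
(7×7/s2, 5×5, 3×3, 3×3, 3×3; max-pool after stages 1, 2 and 5), two
hidden FC layers (256, 128), softmax over human/animal/background.
This configuration has ~25× fewer parameters than the same topology at
the unreduced AlexNet counts [96, 256, 384, 384, 256] — the point of
the reduction is CPU-speed classification. Kernel sizes and pooling
placement beyond the filter counts are a design choice here (standard
AlexNet kernels adapted to the 96-px input).

The network, its im2col convolutions and the Adam trainer are written
directly in NumPy: at desk scale (1,800 training patches) an epoch
takes ~30 s on one CPU and the run is bit-reproducible given a seed.
Training uses softmax cross-entropy, Adam at lr 1e-3, batch 32, 6
epochs (the synthetic task converges by epoch 2; the margin is for
harder inputs), 15% stratified holdout when no explicit validation
split is given.

Class imbalance is handled by oversampling minority classes to the
majority count with **color-modified** copies — grayscale conversion,
per-channel gain in [0.6, 1.4], or a non-identity channel shuffle —
never raw duplicates. Camera-trap corpora are full of grayscale (IR)
and color-distorted images; training on color-perturbed variants pushes
the network toward shape and texture rather than color.

A proposal becomes a detection iff the argmax class is not background;
no additional score cutoff is applied by default (one is exposed in
`RunConfig.score_min`).

## Sequence pooling

Same-class detections in different frames link when their boxes overlap
at IoU ≥ `link_iou` = 0.3; links are transitive. Components supported
by fewer than `min_support` = 2 distinct frames are discarded —
one-frame flicker misclassifications die here even when the classifier
is fooled. Sequences shorter than `min_support` frames keep all
detections, since corroboration is impossible. The label rule is:
background if nothing survives; animal if any surviving detection is an
animal; human otherwise. Raising `min_support` never increases the
verified set.

## Evaluation conventions

A prediction is a true positive iff it matches an unmatched
ground-truth box of the same class at IoU ≥ 0.5 (the boundary counts as
a match); matching is greedy by descending IoU, which is
order-invariant and, on frames with ≤ 5 boxes, within one match of the
exhaustive optimal assignment in randomized tests. The sequence-level
rates are recall = TP/(TP+FN), precision = TP/(TP+FP),
**FNR = FN/(FN+FP)**, TNR = TN/(TN+FP), accuracy = (TP+TN)/total.
The FNR denominator is deliberate — it is the convention this filtering
report format uses — and the conventional miss rate FN/(FN+TP) is
available behind `conventional_fnr=True`. Ratios with zero denominator
are reported as NaN, never as 0. Both the 3-class sequence confusion
matrix and binary object-vs-background metrics are emitted, since a
deployment summary can be read either way.

## Synthetic fixtures

The generator renders what makes real deployments hard, at desk scale:
bursts of 10 frames at 512 × 384, a static textured background per
sequence, 0–1 moving sprites, clumped wind-flicker blocks whose
position and orientation change every frame, a drifting saturated
sunspot present in frames 3–7 of its sequence, one night (grayscale IR)
sequence, σ = 2 Gaussian sensor noise, JPEG quality 95, EXIF
DateTimeOriginal plus filename-encoded timestamps (1–5 s gaps within a
sequence, 10 min between sequences). The default deployment is 6
sequences: 2 animal, 1 human, 3 background. All randomness flows from
one seed; outputs are byte-identical per seed, and per-frame boxes and
labels are recorded by construction.

Two renderer choices are load-bearing and worth stating:

* **Background texture has strong local contrast** (fine-scale
  gradients well above noise), like foliage. On smoother backgrounds
  gradient orientations are noise-dominated and no histogram method can
  hold a block stable between frames.
* **Sprites are heterogeneous, not periodic.** Any spatially
  stationary texture (straight stripes, uniform noise) has a
  translation-invariant orientation histogram, so two frames of a
  *moving* sprite look identical at a co-located block and the MFD can
  adopt the sprite as background. Real animals are heterogeneous —
  outline, limbs, head, pelage all differ along the body — and the
  sprites emulate that with concentric elliptical banding plus a few
  oriented patches: animals wide, brown, coarse-banded; humans tall,
  dark, fine-banded with a skin-toned head.

What the fixtures do **not** emulate: photographic appearance (real
pelage, occlusion, shadows), exposure and white-balance drift between
frames, rain/fog, multi-animal sequences, animals that never move, or
camera-brand EXIF quirks. Passing tests therefore demonstrate that the
pipeline's machinery is correct and well-calibrated under its stated
noise model — not field-grade accuracy on real imagery, which depends
on training the classifier on real labeled patches at scale.

## Problem sizes

The test suite and the acceptance script generate 600 training + 200
test patches per class and train for 6 epochs (~3 min), render the
6-sequence deployment (~2 s), and run detection end to end (~2 s per
deployment). Oracle sweeps use 1,000 random patches (SHL) and 500
random stacks (MFD). These sizes were chosen so a full from-scratch run
completes in minutes on a single CPU while keeping every class and
nuisance represented.

## Known limitations

* Localization is block-quantized (16 px at working resolution);
  IoU against tight ground truth tops out around 0.8.
* The 3-frame method degrades on objects that traverse a block in
  fewer than 3 frames; composite is the default for 10-frame bursts.
* An animal that never moves is invisible to background subtraction
  by design; nothing downstream can recover it.
* MFD assumes each block is background in at least two frames; an
  object loitering over one block for most of a burst can invert the
  exemplar there.
* The trained checkpoint shipped by `trapscan train` on synthetic
  patches is for pipeline validation; real deployments need a model
  trained on real labeled patches.
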