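# Methods

This note documents the models, procedures and numerical choices behind
`lwheatnet`, and what the synthetic experiments do and do not demonstrate.

## Architecture

The classifier is a ShuffleNet-V2-style stacked inverted-residual network
with a parallel mixed attention module, sized for 5-class wheat-seed images.

**Backbone.** Input 224×224×3 (any even size ≥ 32 works; the synthetic
experiments use 64). Stem: 3×3 stride-2 convolution to 24 channels, BN,
ReLU (224 → 112), then 3×3 stride-2 max pooling with padding 1 (112 → 56).
Three core layers follow, each one downsampling unit plus (3, 7, 3) basic
units at widths (116, 232, 464) — the ShuffleNet-V2-1.0× layout. A 1×1
convolution lifts to 1024 features (BN, ReLU); global average pooling,
dropout p = 0.4 and a fully connected layer produce the 5 logits; softmax is
applied at inference. All convolutions are bias-free and BN-followed except
the attention convolutions (below) and the FC layer.

**Basic unit** (stride 1): channel split into halves; the left half passes
through untouched; the right half runs 1×1 conv → BN → ReLU → 3×3 depthwise
conv → BN → 1×1 conv → BN → ReLU, all width-preserving; concat; 2-group
channel shuffle. **Downsampling unit** (stride 2): no split; left branch
3×3 depthwise stride-2 → BN → 1×1 conv → BN → ReLU, right branch the basic
right branch with its depthwise stage at stride 2; each branch emits half
the output width.

**Attention.** ECA computes per-channel gates by a shared-weight, bias-free
1-D convolution across the globally pooled channel descriptor, with
adaptive odd kernel k = |log₂(C)/γ + b/γ|_odd, γ = 2, b = 1. At a tie
(e.g. t = 6) the larger odd value is taken; the result is clamped to ≥ 1.
TPSA pools the input to a 1×1×C descriptor, reduces to max(1, ⌊C/16⌋)
channels (1×1 conv, bias), runs parallel 3×3 and 5×5 same-padding
convolutions (biases) whose outputs are summed, expands back to C (1×1
conv, bias) and gates through a sigmoid. On a 1×1 descriptor the multi-scale
kernels act through their centre taps; a `spatial_tpsa` switch instead
applies the reduction and two-path convolutions to the full-resolution map,
yielding an H×W gate with an identical parameter count. The mixed module
returns eca(x) + tpsa(x) (full variant), tpsa(x) (+tpsa variant) or x
(backbone).

**Placement.** Mixed attention is inserted after core layers 2 and 3
(C = 232 and 464). This placement, with floor-divided reduction and biased
attention convolutions, is what yields the 1.33M total alongside the
backbone's 1.26M; attention at the stem (C = 24) is configurable but adds
only ~10² parameters. Exact counts with the default configuration:
1,258,729 (backbone), 1,328,220 (+TPSA; the two modules add 13,434 and
56,057), 1,328,230 (full; ECA adds two k = 5 kernels).

## Training

Cross-entropy loss (probabilities clamped at 1e-12 before the log), mean
over the batch. Momentum SGD in the exponential-moving-average form
V_t = βV_{t−1} + (1−β)g with β = 0.9 and θ ← θ − ηV_t, with weight decay
4e-5 added to the gradient first. Note this form scales updates by (1−β)
relative to the common `V = βV + g` accumulator; a config flag selects the
common form but the EMA form is the default. The learning rate follows
cosine annealing with warm restarts between fractions 1.0 and 0.01 of the
base rate 3e-3 over a 50-epoch cycle; a run of fewer epochs simply uses the
early part of the cycle. Batch size 16, 50 epochs by default.

Initialisation is Kaiming fan-out normal for all conv and FC weights, BN
scale 1 / shift 0, zero biases, from a seeded generator recorded in the
model config. The fan-out-initialised FC head starts with large logits;
under the EMA optimiser the resulting large early errors act as an implicit
warmup and measurably accelerate the first epochs, so this is kept
deliberately. BN uses eps 1e-5; running statistics are seeded from the
first training batch and then tracked with momentum 0.1, which keeps
evaluation mode meaningful even after very short runs.

All randomness (shuffling, dropout, augmentation crops, synthetic
rendering) flows from explicit NumPy generators seeded in the configs:
identical seeds give bit-identical histories, parameters and reports.

## Data conventions

Images live in one folder per variety; filename stems are three dash- or
underscore-separated integers, the last being the shooting angle (1 groin
up, 2 groin down). The 8:1:1 split allocates, per class of n images,
train = ⌊0.8n⌋ + 1, val = ⌊0.1n⌋, test = the remainder — the rule that
reproduces the published partition (801/100/99 per 1000-image class,
804/100/100 for 1004; totals 4008/500/496). Membership is a per-class
seeded shuffle. Because grains are photographed from two angles, the
default random split can place the two views of one grain in different
splits (as in the source data); `group_by_grain` assigns whole grains to
one split for leakage-free evaluation.

Training images receive a seeded random resized crop (area 0.75–1.0, aspect
0.85–1.18) — gentle, because the subject is a single centred grain that
must stay in frame — then per-channel normalisation with the ImageNet
statistics (overridable). Validation/test images are resized only. The crop
is drawn once per image when arrays are materialised, not re-sampled every
epoch; with the short training budgets used here this is simpler and fully
deterministic.

## Synthetic data

The generator emulates the real dataset's *structure*: a single centred
grain on a near-black background (level 0.03 plus Gaussian noise, σ = 0.02
by default), five variety styles, two angles per grain, balanced counts,
and the folder/filename conventions. A grain is a rotated shaded ellipse
with sinusoidal texture along its axis; groin-up images additionally show a
darkened longitudinal crease. All draws are made before the angle is
consulted, so the two views of a grain differ only in the crease region.
The five default styles are pairwise distinct in colour, elongation and
texture frequency, with colours spread across hue space so that a
nearest-centroid classifier on mean RGB already separates the classes
(probe accuracy ≈ 0.98 at the default conditions) — the generator's signal
guarantee for downstream training tests.

What passing the synthetic experiments shows: the full pipeline (render →
scan → split → preprocess → train → evaluate) is correct, deterministic and
able to fit a clearly separable 5-class problem within a small budget. What
it does not show: performance on real wheat images, whose classes differ
far more subtly; the published real-data accuracies are not reproducible
without the authors' images.

## Problem sizes

The synthetic training experiments run at 64×64 resolution with 50 images
per class (205 training images after the split) for 10 epochs — about half
a minute per variant on one CPU with this NumPy implementation — and reach
≥ 0.95 test accuracy for the full variant and ≥ 0.9 for all three variants
across seeds. The smoke preset (20 images per class, 3 epochs) is a
plumbing and determinism gate only; 18 optimiser steps are not enough to
learn, and its reported accuracy is expected to be near chance. Parameter
counting and the split rule are exact at any size.

## Known limitations

- The appearance model is far simpler than real grain imagery; results on
  the synthetic task bound nothing about real-data accuracy.
- The EMA momentum form at the published learning rate yields small
  effective steps; long schedules (the default 50 epochs) are sized for it.
- Single-threaded NumPy: training at 224×224 on thousands of images is
  possible but slow (minutes per epoch); the package is sized for method
  verification, not production training throughput.
- `group_by_grain` may deviate from the printed split counts by up to one
  grain per split boundary, since grains move between splits as wholes.
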