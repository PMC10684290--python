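# Methods

This note documents the model, the numerical choices, and the synthetic-data
conditions behind `cdmenet`, at the level of detail a maintainer needs to
judge what the tests do and do not establish.

## Model and assumptions

The counter is a density-map regressor: every annotated object centre
contributes a unit-integral isotropic Gaussian bump (σ, default 15 px), so the
map's integral is the (fractional) object count. The assumption doing the work
is that a fixed kernel width is adequate — appropriate for berries, whose
apparent size varies far less than, say, people in perspective crowd scenes.
Bumps are sampled at pixel centres, normalised over their untruncated ±4σ
window, and clipped at the image border without renormalisation; an interior
point therefore contributes exactly 1.0 and a border point less (the tests'
1% conservation tolerance covers discretisation only, not border loss).

The network is a VGG16-style stack (stages of 64/128/256/512 channels,
depths 2-2-3-3, three 2×2 max-poolings) followed by two 3×3 convolutions with
dilation 2 (512, then 256 channels), all at 1/8 of the input resolution. Heads
are deliberately minimal: the density regressor is a linear 1×1 convolution to
one channel; each of the k density-level predictors is a 1×1 convolution with
a sigmoid. Ground truth is produced at full resolution and reduced by
sum-preserving 8× block summation, so the count is exactly preserved and all
losses compare maps at the network's own resolution. `width_scale` multiplies
every channel width (floor 1) without touching the topology; a 1/16-width
variant trains in seconds per epoch on one CPU and is what the test suite
uses. Inputs with sides not divisible by 8 are zero-padded right/bottom and
the outputs cropped back. Images are normalised per channel to [0, 1]; no
pretrained weights are used anywhere, so everything is reproducible from a
seed.

Because the environment provides no deep-learning framework, `cdmenet.nn`
implements the needed primitives directly in NumPy — convolution (as a sum of
shifted views per kernel tap, which makes dilation free), 2×2 max-pooling,
sigmoid/ReLU, hand-derived backward passes, and Adam with the usual defaults.
Gradient correctness is pinned by finite-difference tests through the whole
network and through each loss.

## Density levels and thresholds

The strictly positive values of the labeled, already-downsampled density maps
are pooled and sorted ascending into {d_p} (length T). The threshold at
quantile position S is the value at 1-based index clamp(⌈S·T⌉, 1, T); with the
default positions {0, 0.33, 0.66, 1} this yields c = 4 thresholds and k = 3
levels. Pooling happens *after* downsampling deliberately: block summation
scales per-pixel values by ~64, and thresholds must live on the same scale as
the maps they partition. Level j covers (t_j, t_{j+1}], except that the lowest
interval opens at 0 rather than at the S = 0 threshold — otherwise pixels at
exactly the minimum nonzero density would belong to no level. Ties on the
closed upper bound resolve to the lower level. Thresholds are computed from
labeled images only and frozen (the `prepare` CLI step caches them), so
unlabeled statistics can never leak into the supervision targets.

## Pseudo-labels and the zero-fire decision

On unlabeled images, a level predictor fires where its probability strictly
exceeds t_p = 0.8. Exactly one firing predictor makes the pixel foreground of
that level; two or more firing predictors contradict the density-mutual-
exclusion prior and the pixel is excluded from supervision. What a pixel with
*no* firing predictor contributes was a genuinely open design point, and the
two readings behave very differently:

* treating zero-fire pixels as *valid background* turns the predictors' own
  early, cautious outputs into all-background targets; the cross-entropy then
  pushes every probability down, no pixel ever crosses t_p, the mechanism
  never engages, and the unlabeled stream degrades the shared features
  (observed directly: validation MAE 3–10× worse than labels-only);
* *excluding* them leaves unlabeled supervision to confident,
  non-contradictory pixels only; confidence first emerges from the labeled
  images and is then reinforced and structured (via the density-difference
  loss) on the unlabeled ones.

The package defaults to exclusion (`PseudoLabelConfig.zero_fire="exclude"`);
the background reading remains available for sensitivity analysis.
Pseudo-labels are regenerated at every step from the current predictions, are
constants with respect to the gradient, and are never persisted. A training
step whose total gradient is exactly zero (an unlabeled image with all pixels
excluded) skips the optimiser update — applying Adam's stale momentum dozens
of times between informative steps measurably corrupts training.

## Losses

All printed objective terms are pixel/column *sums*, and the implementation
keeps them on that common scale: the density MSE is the squared L2 norm summed
over pixels (averaged over the batch, which is size 1); the auxiliary
cross-entropy is a standard binary cross-entropy, masked by the validity map,
summed over valid pixels and averaged over the k levels (a per-pixel-mean
variant exists behind `normalize_pixels=True` for diagnostics); the
density-difference loss sums cosine similarities of map columns without width
normalisation, −(1/k)-weighted for matched levels and +1/(k(k−1))-weighted
across levels. Cosine similarity carries ε = 1e-8 in the denominator rather
than a zero-vector branch, keeping it differentiable; an all-zero column has
similarity 0. Probabilities are clipped to [1e-7, 1−1e-7] before logarithms,
and the clipped region's gradient is zero. Columns (not rows) are the feature
vectors by default; `extract="rows"` is available for sensitivity checks.
Loss weights default to λ1 = λ3 = 0.01 and λ2 = λ4 = 1.

## Training protocol

Each epoch visits the shuffled union of labeled and unlabeled images once,
batch size 1 (an alternating sampler is available). Labeled steps optimise
MSE + λ1·CE + λ2·DD against ground-truth targets built on the fly from the
augmented crop; unlabeled steps optimise λ3·CE + λ4·DD against fresh
pseudo-labels and therefore cannot move density-head-exclusive parameters
(asserted numerically in the tests). Augmentation is a uniform random crop
(full-scale default 1296×864) with points re-referenced and out-of-crop points
dropped, plus a horizontal flip with probability 0.5 (x → w−1−x, clamped into
frame for fractional coordinates near the border; vertical flips are
unnatural for vineyard rows and are not used). The learning rate is
initial_lr·0.5^⌊epoch/30⌋ (full-scale default 1e-6) under Adam with library
defaults. When a validation set is supplied, per-epoch MAE is tracked and the
best-MAE parameters are retained and checkpointed. With a fixed seed the loop
is bit-reproducible on one device.

## Synthetic scenes

The generator is a Thomas-like cluster process: cluster centres uniform in
frame, berries Gaussian-scattered around them, rendered as shaded,
colour-jittered disks over a smooth textured background, with per-image
choices of berry colour family (three cultivar-like palettes) and a global
illumination gain. It targets the statistical preconditions of the method —
tightly clustered points, several occupied density levels, occlusion, a
background-dominated frame, and enough cross-image heterogeneity that a small
labeled subset does not already determine the task — not photo-realism. Counts
are rejection-sampled into a target range (default 30–200 on 256×256, a
scaled-down analogue of field images carrying roughly 200–1,600 berries).
What passing tests on these scenes show is that the pipeline's mechanics and
the direction of the semi-supervised effect are sound; they say nothing about
absolute accuracy on real field imagery, which depends on backbone capacity,
pretraining and data volume far beyond desk scale.

## Desk-scale study conditions

The comparison exercised by the tests and the acceptance script trains a
1/16-width network on 40 scenes of 96×96 px (15–70 berries, σ = 3, 64×64
crops), 10% labeled, Adam at 3e-3 constant, 80 epochs, validating on 10
scenes — once with the unlabeled images flowing through the auxiliary tasks
and once labels-only, from identical initial parameters. Two conditions were
set by explicit mechanism-activity requirements rather than accuracy: the
learning rate is the value at which level predictors reach pseudo-label
confidence (> t_p) by mid-run, and the horizon is long enough that the
engaged mechanism covers a meaningful fraction of training (confidence first
crosses t_p near epoch 25). Under these conditions the full objective matches
or beats labels-only validation MAE on the tested seeds; the margin is small
and seed-dependent, which is the expected desk-scale shadow of an effect the
full-scale method shows at much larger magnitude.

## Known limitations

* Counts from the raw density head can include small negative pixel values;
  clipping at zero before summation is available but off by default.
* The NumPy network is single-device and unbatched; it is built for
  correctness and desk-scale experiments, not throughput.
* The fixed-σ kernel and the disk-rendering generator do not model scale
  variation within an image.
* R² is reported as undefined (missing) when all true counts coincide.
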