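# Methods

This note documents the models and conventions implemented in
`tumnet`, the choices made where the design was genuinely open, and
what the synthetic phantoms do and do not establish.

## Pixel-level fusion

Given two co-registered 8-bit slices, the fused image is the pixelwise
mean, maximum, or minimum. The mean of two integers is fractional, so
fusion arithmetic is carried out on real-valued intensities; rounding
(half-to-even, then clipping to [0, 255]) happens only when an image is
exported to an 8-bit raster. This avoids double rounding in downstream
metrics. Images of unequal size are rejected rather than resized:
pixel-level fusion is meaningless on unregistered inputs, and a silent
resize would mask a registration fault.

The model-input resize (typically 256x256 -> 227x227) uses bilinear
interpolation with clamping; an image already at the target size is
returned unchanged. Bilinear is the conventional default for intensity
images when no interpolation scheme is otherwise specified.

## The Tumnet classifier

Architecture (227x227x1 input, channels-last):

| stage | layers | activation shape |
|---|---|---|
| 1 | conv 3x3x1x8 "same" / BN / ReLU / maxpool 2x2 s2 | 227x227x8 -> 113x113x8 |
| 2 | conv 3x3x8x16 / BN / ReLU / maxpool | 113x113x16 -> 56x56x16 |
| 3 | conv 3x3x16x32 / BN / ReLU / maxpool | 56x56x32 -> 28x28x32 |
| 4 | conv 3x3x32x64 / BN / ReLU / maxpool | 28x28x64 -> 14x14x64 |
| 5 | conv 3x3x64x128 / BN / ReLU | 14x14x128 |
| head | flatten (25088) / dropout 0.6 / FC / softmax | num_classes |

Pooling geometry is floor((n − f)/s) + 1; the floor is required for
227 -> 113 and reproduces the whole shape chain. Parameter accounting:
conv kh·kw·cin·cout + cout, batchnorm 2·cout, FC classes·25088 +
classes. `num_classes` is configurable: 2 for the tumor/no-tumor task,
6 reproduces the published six-way head (FC count 150534).

Descriptions of this architecture circulate with inconsistent layer
tallies ("3 pooling layers, 3 fully connected layers"); the layer table
with 4 pools and a single FC is the only variant whose activation
shapes and parameter counts are internally consistent, so it is taken
as authoritative.

### Engine

The network is implemented directly in NumPy (float32, channels-last):
3x3 convolution via im2col + BLAS matmul, per-channel batch
normalization (eps 1e-5, running-stat momentum 0.1), 2x2/stride-2 max
pooling that drops odd trailing rows/columns, inverted dropout, and a
dense head. The max-pool backward pass splits the gradient equally
among tied maxima (ties are rare with float activations). Softmax
cross-entropy is computed in float64 for stability.

### Training

- Zero-center normalization: the per-pixel mean image of the training
  split is subtracted from every input; it is stored with the model.
- Split: shuffled 70/30 train/validation (`validation_fraction` 0.30);
  round(n x fraction) validation samples, so n = 100 gives exactly
  70/30.
- Optimizer: SGD with momentum 0.9, learning rate 0.01, batch 16,
  20 epochs. The learning rate was chosen so that the loss on the
  separable phantom task reaches its floor comfortably within the
  180 optimizer steps that 140 training images and 20 epochs provide;
  with batch normalization throughout, 0.01 is stable. All settings
  are overridable in `TrainConfig`.
- Dropout 0.6 between flatten and FC, training only — the conventional
  position for a single pre-classifier dropout.
- Initialization: seeded He-uniform. A single `numpy.random.Generator`
  (from `TrainConfig.rng_seed`) drives initialization, shuffling, and
  dropout masks, so a run is bit-reproducible on a fixed BLAS.
- Validation metrics are computed in inference mode (running BN
  statistics); with few optimizer steps the running statistics lag the
  batch statistics, which is why validation accuracy can trail training
  accuracy for the first few epochs.

## Segmentation

Foreground is `intensity > t` with t from Otsu's between-class-variance
maximization (256 bins) by default, or a fixed value. Components use
8-connectivity (the common default for blob extraction). The tumor
rule is strict: solidity > 0.7 AND area > 100 px; boundary values fail.
All passing components are kept — residual tumor tissue can be
multifocal — and per-component statistics are reported. Physical area
is `pixels x area_factor` with `area_factor` = 0.264 mm²/px by default;
the factor is an opaque calibration constant (its pixel-pitch
provenance is undocumented) and is configurable. The outline overlay
marks `mask & ~erosion(mask)` (3x3 structuring element), a closed
one-pixel-wide boundary.

In the full pipeline, segmentation runs on the fused (or
single-modality) intensity image and is gated on the classifier's
tumor-present decision; `force_segment` bypasses the gate for
evaluation.

## Metrics

- **SSIM**: the standard form
  [(2 mu_x mu_y + C1)(2 sigma_xy + C2)] /
  [(mu_x² + mu_y² + C1)(sigma_x² + sigma_y² + C2)] with
  C1 = (k1 L)², C2 = (k2 L)², k1 = 0.01, k2 = 0.03. Local moments use a
  7x7 uniform window (population covariance); the map is averaged over
  fully valid windows only, which makes the implementation agree with
  `skimage.metrics.structural_similarity(win_size=7,
  gaussian_weights=False, use_sample_covariance=False)` to machine
  precision — that agreement is asserted in the tests as an independent
  cross-check. L defaults to 255 for 8-bit images (the conventional
  dynamic range; a legacy convention setting L = 8 for 0–255 images
  exists, so L is configurable). A single-window global mode is
  available via `SSIMParams(windowed=False)`.
- **Entropy**: −Σ p(k) log2 p(k) over the 256-bin histogram (with the
  conventional negative sign, so constant images give 0 bits and a
  uniform histogram gives 8), 0·log 0 ≡ 0.
- **Rates**: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
  (TP+TN)/total, on pixelwise confusion counts by default (slice-level
  counts can be supplied the same way). Zero denominators raise
  `UndefinedMetricError` rather than silently returning 0.
- **First-order statistics** use the population convention; the
  normalized variant scales intensities by 1/255 first.

## Synthetic phantoms

Each phantom pair shares one anatomy on a 227x227 grid: an elliptical
brain (semi-axes 88x72 px), a thin skull ring just outside it, and
optionally a compact tumor ellipse. The MRI-like slice has mid-dark
tissue (base 45) with smooth Gaussian-filtered texture (amplitude 12)
and a faint skull (65); the CT-like slice has nearly flat dark tissue
(15) and a bright skull ring (240). The tumor (default intensity 230,
semi-axes 14x11 px ≈ 480 px area) appears identically placed in both
modalities, with a 1-px Gaussian-smoothed rim so its solidity stays
above 0.9. Additive Gaussian noise (default sigma 5, a mild level
consistent with preprocessed atlas slices) is applied per modality;
a salt-and-pepper mode exists for robustness tests only. The ground
truth mask is the exact rasterized ellipse before rim smoothing.

The contrasts are chosen so that on the average-fused image the
intensity histogram has a dominant dark mode (background + tissue,
≲ 60) and a sparse bright mode (skull + tumor, ≳ 150): Otsu then cuts
between them, and the solidity filter removes the ring-shaped skull
(solidity ≈ 0.14), leaving the tumor. Distractor options plant small
bright blobs (area ≤ 100 px) and a low-solidity cross to exercise the
rejection rules.

`generate_dataset` randomizes tumor geometry (center within the brain,
semi-axes 10–16 x 8–13 px, orientation, intensity 215–245) and texture
per sample, with per-sample seeds spawned from one master seed.

What passing tests on these phantoms show: the pipeline's mechanics —
fusion arithmetic, threshold selection, component filtering, area
accounting, learnability of a bright-blob class difference — are
correct and reproducible. What they do not show: performance on real
MRI/CT anatomy. The phantoms model no MR sequence or CT physics, no
partial-volume effects, no registration error, and a deliberately
separable class structure; accuracy numbers on phantoms therefore do
not transfer to clinical data.

## Problem sizes and determinism

The test suite and the acceptance script train on 200 phantoms for 20
epochs (about four minutes on one CPU core) and evaluate segmentation
on 50 noiseless phantoms; these sizes give stable, seeded results while
keeping a full run inside a coffee break. Every stochastic step
(phantom generation, splitting, initialization, dropout) derives from
explicit integer seeds.

## Known limitations

- 2-D slices only; no volumetric segmentation or 3-D context.
- Threshold segmentation assumes the tumor is among the brightest
  compact structures of the working image; hypointense lesions are out
  of scope.
- The CNN engine is single-threaded NumPy; it is meant for small
  inputs and full inspectability, not for large-scale training.
- The 0.264 mm²/px area factor is a fixed calibration; reported
  areas are only as physical as that constant.
- No image registration is performed or verified; inputs are assumed
  co-registered.
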