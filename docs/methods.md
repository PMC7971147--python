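# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind microdl, in the spirit of a package methods section:
what is computed, under which assumptions, and what the bundled tests do and
do not demonstrate.

## Pipeline model

A run is fully specified by twelve parameters (task, data path, seed,
pretrained weights, batch size, epochs, augmentations, loss, number of
classes, resize, uncertainty flag, evaluation flag). Only task and data path
are mandatory; the defaults are seed 1, batch size 1, 100 epochs, no
augmentation, the task's canonical loss (binary cross-entropy for
segmentation, categorical cross-entropy for classification, mean squared
error for regression), two classes, no resizing, no uncertainty, automatic
evaluation on. Unknown configuration keys are rejected rather than ignored.

Every random stream — validation split, epoch shuffling, augmentation
sampling, weight initialisation, dropout masks, uncertainty passes — derives
from the seed through independent, purpose-keyed generators
(`derive_rng(seed, "shuffle", epoch)` etc.), so a rerun with the same config
reproduces the batch composition bitwise and, on the same hardware, the same
loss trajectory. Semantic segmentation is strictly two-class
(background/foreground); its continuous output is binarized per image with
Otsu's method on a 256-bin histogram, which adapts the operating point to
each image's output calibration.

## Networks and training

The networks run on a small numpy engine written for this package:
convolution (im2col + matmul, zero "same" padding), 2×2 transposed
convolution, 2×2 max-pooling, inverted dropout, dense layers, softmax, and
Adam, each with an explicit backward pass. Arrays are `(N, C, H, W)`
float32; parameters are He-initialised.

**U-Net.** Default depth 2 with 16 base filters doubling per level, two
3×3 conv + ReLU per block, transposed-convolution upsampling, dropout
(rate 0.25) at the end of each encoder block and the bottleneck, and a 1×1
output convolution. There is no batch normalization: the pipeline's default
batch size is 1, where batch statistics are ill-defined, and the desk-scale
problems converge without it. Inputs whose sides are not divisible by
2^depth are reflect-padded and the output cropped back, so output shape
always equals input shape. The depth/width defaults are deliberately small —
they train on one CPU in minutes and the default blob scenes are within
their receptive field; both are constructor arguments for larger problems.

**Residual classifier.** `layout="resnet50"` builds the canonical
bottleneck network with exactly 50 weight layers (stem + 3/4/6/3 three-conv
blocks + dense); `layout="lite"` (the pipeline's default for training) is a
three-stage basic-block network with a stride-2 stem. Dropout 0.2 follows
each residual stage and dropout 0.5 precedes the final dense layer; these
placements give the classifier a stochastic path for Monte-Carlo
uncertainty, since the canonical residual layouts contain none.

**Training.** Adam with lr 1e-3, betas (0.9, 0.999). The spec-level
convention of "iterations over the dataset" maps to epochs. Early stopping
monitors the validation loss with patience max(5, epochs/10) and min-delta
1e-5; the best epoch's weights are checkpointed (`logs/best_model.npz`) and
restored at the end, and per-epoch losses go to `logs/training_log.csv`.
A non-finite loss aborts with the epoch and batch named. The 20 % validation
split is `max(1, round(0.2 n))`, drawn from the sorted identifiers so it is
invariant to discovery order.

**Losses.** mse = mean (p−t)²; bce = −mean[t ln p + (1−t) ln(1−p)] with p
clipped to [1e-7, 1−1e-7]; cce = −mean over the batch of Σ_c t_c ln p_c.
Gradients are taken with respect to the network output and propagated
through the sigmoid/softmax head, with the same clipping.

**Transfer learning.** Checkpoints are flat name → tensor archives. Loading
matches layer-wise: a layer (all tensors sharing a name prefix) is copied
only if every tensor matches in name and full shape; partial layer matches
(e.g. a bias that coincidentally keeps its shape when the layer widens) are
skipped with the layer. The manifest of loaded and skipped entries covers
the whole archive and is echoed into the run log.

## Augmentation

Spatial operators (horizontal/vertical flip, rotation ±20°, zoom 0.9–1.1)
apply the identical geometric map to image and image-valued label; labels
that are binary are interpolated nearest-neighbour and re-binarized, images
bilinearly with reflect padding. Color operators (brightness ±0.1, contrast
0.8–1.25, gamma 0.7–1.4, Poisson noise at photon scale 255, per-image
min-max rescale, z-scoring, down-up resampling by a factor up to 2) touch
the image only and clip back to [0,1], except z-scoring which deliberately
leaves zero-mean/unit-variance scale. Each operator fires independently
with probability 0.5 by default; all ranges and probabilities are
overridable through the config's `augmentations` mapping. Transforms are
sampled from a generator keyed by (seed, epoch, sample index), are plain
serializable dicts, and can be written out as TIFF pairs for visual
inspection. Regression targets are treated like continuous labels: spatial
operators transform them, color operators never do.

## Uncertainty

Monte-Carlo dropout keeps the dropout units live at inference and draws
T = 20 stochastic passes (configurable). The per-pixel uncertainty map is
the population standard deviation across passes — the standard epistemic
summary; predictive entropy would be an alternative and the map choice is
the one genuinely open design point here. The scalar per-image summary u is
the mean of the map. For classification the score is the normalized
predictive entropy H(p̄)/ln C of the mean softmax vector, which meets the
anchor points exactly: unanimous one-hot passes give 0, a uniform mean
gives 1. Distributions of scores (e.g. correct vs. incorrect predictions,
clean vs. corrupted inputs) are compared with the Mann-Whitney rank test.
A model whose dropout rate is 0 still supports the procedure and yields an
identically-zero map; only a model without dropout units at all is a
contract violation.

## Evaluation

Per test image: Jaccard index over pixels (both-empty defined as 1.0 —
perfect agreement on absence), pixel accuracy, mean absolute error, mean
relative error with ε = 1e-8 in the denominator, and pixel-wise Pearson r
(reported as `undefined` against a constant truth rather than NaN). For
classification: Jaccard, MAE and MSE on the label indices, the confusion
matrix, ROC by threshold sweep and trapezoidal AUC (macro one-vs-rest for
more than two classes). Metric spread over a finite test set is estimated
by subsample bootstrapping: 100 rounds, each the median of half the
per-image values drawn without replacement — a subsample scheme rather than
a classical with-replacement bootstrap, matching the "half of the test set"
protocol. Standard implementations back the generic steps (scikit-image for
Otsu and connected components, scikit-learn for ROC/AUC/confusion matrix,
scipy for the rank test); the test suite checks each against independent
brute-force oracles (exhaustive pair counting for AUC and U, exhaustive
bin search for Otsu, scalar loops for the pixel metrics).

## Synthetic study conditions

The generator emulates fluorescence-microscopy-like scenes: 64×64 images
with 1–6 non-overlapping bright blobs (radius 4–9 px, foreground mean 0.8,
background 0.2, Gaussian noise sd 0.08). Ground truth is exact by
construction. The regression target is a Gaussian ridge (σ = 1.5 px) on the
blob boundaries computed from the noiseless mask — a deterministic
image-to-target mapping that stands in for envelope-staining prediction.
Classification classes differ by planted blob count (base range 1–3,
shifted by round(k·separation); the studies use separation 4, which makes
the count ranges disjoint). Out-of-distribution corruption applies blur,
partial contrast inversion and noise scaled by a severity in [0,1], with
severity 0 the bitwise identity. 3D stacks (8 slices, ellipsoidal blobs
spanning 3–5 slices) exercise the multi-page TIFF pathway; stacks are
trained and predicted slice-wise through the 2D networks — a true
3D-convolution variant is not implemented.

The bundled studies train on 100 scenes and evaluate on 30 (50 per class
for classification), for ~25 training epochs at batch size 8. On one CPU
each study takes 1–2 minutes. These scenes are intensity-separable and
noise-limited in a way real microscopy rarely is: passing them certifies
that the pipeline's plumbing, optimization, thresholding, uncertainty and
evaluation machinery are correct, not that the default networks reach
state-of-the-art accuracy on real stained tissue or heterogeneous
acquisitions. The out-of-distribution uncertainty contrast is likewise a
qualitative property (corrupted inputs score significantly higher u), not a
calibrated uncertainty.

## Known limitations

- No GPU path and no batch normalization; very deep configurations (the
  50-layer classifier) are constructible and testable but impractical to
  train in this engine.
- The instance backend is detection-by-segmentation; touching objects that
  merge into one connected component are not separated (no watershed or
  region-proposal stage). A heavyweight detector can implement the same
  `InstanceSet` contract.
- Classification AUC for more than two classes is macro one-vs-rest by
  choice; no probability calibration is performed.
- Multi-channel TIFF axis inference follows the page-axis = Z, trailing
  small axis = channels convention; exotic axis orders need pre-conversion.
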