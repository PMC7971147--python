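# microdl

A config-driven deep-learning pipeline for biomedical images, covering the
four workhorse tasks of microscopy image analysis:

- **semantic segmentation** — per-pixel foreground/background labelling
  (encoder-decoder U-Net, sigmoid head, Otsu-thresholded output),
- **instance segmentation** — one mask per object
  (detection-by-segmentation: semantic network → Otsu → connected components),
- **pixel-wise regression** — continuous per-pixel targets such as in-silico
  staining (same U-Net, linear head, MSE loss),
- **image classification** — residual network with softmax output.

The pipeline is aimed at researchers who want to apply these methods to their
own image folders without writing training code: a single JSON configuration
file with at most twelve parameters (only the task and the data path are
mandatory) drives data import, normalization, a seeded 20 % validation split,
paired online augmentation, Adam training with early stopping, test-set
prediction, Monte-Carlo-dropout uncertainty estimation, and automated
quantitative evaluation.

Everything runs on a plain CPU. The networks are implemented on a compact
numpy engine with explicit forward/backward passes (convolution, transposed
convolution, max-pooling, dropout, dense, Adam), sized so that the bundled
synthetic datasets train in minutes.

## The models in brief

**U-Net.** A symmetric contractive/expansive convolutional network with skip
connections. All convolutions are zero-padded so the output spatial shape
equals the input shape; dropout sits at the end of every encoder block, which
is what makes Monte-Carlo uncertainty possible later. The sigmoid head emits
per-pixel probabilities p(x) ∈ (0,1); segmentation masks are obtained by
thresholding p with Otsu's method (maximizing the between-class variance of a
256-bin histogram of p). With a linear head the same network performs
pixel-wise regression under L(p,t) = mean (p−t)².

**Residual classifier.** Residual blocks with identity shortcuts; the default
layout is the canonical 50-weight-layer bottleneck network, with added
dropout after each residual stage and before the final dense layer. A
reduced-depth `lite` layout (basic blocks, used by the pipeline default) is
trainable on CPU in seconds.

**Monte-Carlo dropout.** At inference the dropout units are kept live and
T = 20 stochastic passes are drawn. For image tasks the per-pixel population
standard deviation across passes is the uncertainty map and its mean is the
scalar average pixel uncertainty u; for classification the score is the
normalized predictive entropy H(p̄)/ln C ∈ [0,1] of the mean softmax vector
(0 = certain, 1 = maximally uncertain).

**Transfer learning.** Weights are stored as a flat name → tensor archive;
on load, each layer is matched by name and full shape and loaded only if all
of its tensors fit, everything else is skipped — the manifest of loaded and
skipped layers is reported in the logfile.

## Data layout

```
<path>/train/image/         input images (TIFF/PNG, 8/16-bit, 2D or stacks)
<path>/train/groundtruth/   labels with identical filenames,
                            or labels.csv ("filename,label") for classification
<path>/test/image/
<path>/test/groundtruth/
```

Input and ground-truth files are paired strictly by identical filename.

## Worked example

```bash
# generate a synthetic nuclei-like dataset (20 train / 8 test images)
microdl fixtures /tmp/demo --task semantic_segmentation --n-train 20 --n-test 8

# configure and run
cat > /tmp/demo/config.json <<'JSON'
{"use_algorithm": "semantic_segmentation",
 "path": "/tmp/demo",
 "Iterations_Over_Dataset": 12,
 "batchsize": 4,
 "seed": 1}
JSON
microdl run /tmp/demo/config.json
```

Output (abridged):

```
data: 16 train / 4 validation / 8 test samples
epoch 1/12  train=0.7453  val=0.6676
epoch 2/12  train=0.6254  val=0.5490
...
epoch 11/12  train=0.0876  val=0.0414
epoch 12/12  train=0.0709  val=0.0407
done; log written to /tmp/demo/logs/run.log
```

The per-epoch numbers are the mean binary cross-entropy on the shuffled
training batches and on the held-out validation split; training keeps the
checkpoint of the epoch with the lowest validation loss. Afterwards
`/tmp/demo/results/` contains one continuous probability map and one
Otsu-binarized mask per test image, and `/tmp/demo/evaluation/` holds
`metrics_per_image.csv` (Jaccard index, pixel accuracy, mean absolute and
relative error, Pearson r per test image), the aggregate summary with
subsample-bootstrap percentiles, and rendered panels (image / ground truth /
prediction / error map), boxplots, and — for classification — the confusion
matrix and ROC curve.

The run above reaches a median test Jaccard of 0.85 after its 12 epochs
(`evaluation/metrics_summary.json`; longer schedules reach ≈ 0.99): the
synthetic scenes are deliberately learnable, so the number mainly certifies
that the whole chain (pairing, normalization, training, thresholding,
evaluation) is wired correctly.

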