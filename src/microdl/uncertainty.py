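"""Test-set prediction, Otsu thresholding, Monte-Carlo-dropout uncertainty.

Monte-Carlo dropout keeps the dropout units live at inference and runs T
stochastic forward passes (default T=20), treating the spread of the passes
as an approximation of the model's predictive uncertainty. For image tasks
the per-pixel population standard deviation across passes is the uncertainty
map, and its mean over pixels is the scalar average pixel uncertainty u. For
classification the normalized predictive entropy of the mean softmax vector,
H(p̄)/ln(n_classes) ∈ [0, 1], is the uncertainty score: 0 = all passes agree
on one class, 1 = the mean prediction is uniform over classes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats
from skimage.filters import threshold_otsu as _sk_otsu

__all__ = [
    "predict_test_set", "otsu_threshold", "mc_dropout_predict",
    "pixel_uncertainty", "classification_uncertainty",
    "compare_uncertainty_distributions", "DEFAULT_MC_PASSES",
]

DEFAULT_MC_PASSES = 20


def _forward_sample(model, image: np.ndarray) -> np.ndarray:
    """Deterministic forward pass of one channels-last 2D image or 3D stack.

    Stacks are predicted slice-wise through the 2D network and restacked.
    """
    from .training import _to_input
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] > 4:          # (Z, H, W) stack
        return np.stack([model.forward(_to_input(sl)[None],
                                       stochastic=False)[0, 0] for sl in img])
    if img.ndim == 4:                                 # (Z, H, W, C) stack
        return np.stack([model.forward(_to_input(sl)[None],
                                       stochastic=False)[0, 0] for sl in img])
    return model.forward(_to_input(img)[None], stochastic=False)[0, 0]


def predict_test_set(model, test_pairs, task: str, outdir,
                     class_names=None, log=print) -> dict:
    """Point predictions (dropout off) for every test sample, written to disk.

    Image tasks save the continuous prediction (``pred_<name>.tif``) and, for
    segmentation, the Otsu-binarized mask (``mask_<name>.tif``).
    Classification appends one row per image to ``results.csv`` with the
    predicted label and per-class probabilities. Returns
    identifier -> prediction (probability vector for classification).
    Shape-incompatible images are skipped with a logged warning.
    """
    from pathlib import Path

    import pandas as pd

    from .data import write_prediction
    from .training import _to_input

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    predictions: dict[str, np.ndarray] = {}
    rows = []
    for pair in test_pairs:
        try:
            if task == "classification":
                probs = model.forward(_to_input(pair.image)[None],
                                      stochastic=False)[0]
                predictions[pair.identifier] = probs
                row = {"filename": pair.identifier,
                       "predicted_label": class_names[int(probs.argmax())]}
                row.update({f"prob_{c}": float(p) for c, p in zip(class_names, probs)})
                rows.append(row)
                continue
            pred = _forward_sample(model, pair.image)
            predictions[pair.identifier] = pred
            write_prediction(f"pred_{pair.identifier}", pred, outdir)
            if task in ("semantic_segmentation", "instance_segmentation"):
                _, binary = otsu_threshold(pred)
                write_prediction(f"mask_{pair.identifier}", binary, outdir)
        except ValueError as exc:
            log(f"warning: skipping {pair.identifier}: {exc}")
    if task == "classification" and rows:
        pd.DataFrame(rows).to_csv(outdir / "results.csv", index=False)
    return predictions


def otsu_threshold(probability_map: np.ndarray):
    """Otsu's method on a 256-bin histogram of a [0, 1] probability map.

    Returns ``(threshold, mask)`` with ``mask = map > threshold``. A constant
    map has no between-class variance to maximize; the constant is reported
    as the threshold and the mask is all-background.
    """
    pm = np.asarray(probability_map, dtype=np.float64)
    if pm.min() == pm.max():
        return float(pm.min()), np.zeros_like(pm, dtype=bool)
    thr = float(_sk_otsu(pm, nbins=256))
    return thr, pm > thr


def mc_dropout_predict(model, image: np.ndarray, T: int = DEFAULT_MC_PASSES,
                       rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """T stochastic forward passes with independent dropout masks.

    ``image`` is a single ``(C, H, W)`` sample. The model must contain active
    dropout units — without them every pass is identical and the "uncertainty"
    would be a silent zero.
    """
    if T < 2:
        raise ValueError(f"need at least 2 passes, got T={T}")
    if not model.has_dropout:
        raise ValueError("model has no dropout units; Monte-Carlo dropout "
                         "needs a network built with dropout layers")
    if rng is not None:
        model.reseed_dropout(rng)
    x = np.asarray(image, dtype=np.float32)[None]
    return [model.forward(x, stochastic=True)[0] for _ in range(T)]


def pixel_uncertainty(passes: list[np.ndarray]):
    """Per-pixel population standard deviation across passes, and its mean u."""
    if len(passes) < 2:
        raise ValueError("need at least 2 passes")
    shapes = {p.shape for p in passes}
    if len(shapes) > 1:
        raise ValueError(f"passes have mismatched shapes: {sorted(shapes)}")
    stack = np.stack([np.asarray(p, dtype=np.float64) for p in passes])
    umap = stack.std(axis=0, ddof=0)
    # pixels where every pass agrees have exactly zero spread; do not let
    # mean-subtraction rounding leave a 1e-16 residue there
    umap[np.ptp(stack, axis=0) == 0] = 0.0
    umap = umap.astype(np.float32)
    return umap, float(umap.mean())


def classification_uncertainty(passes: list[np.ndarray]) -> float:
    """Normalized entropy of the mean probability vector, in [0, 1]."""
    if len(passes) < 2:
        raise ValueError("need at least 2 passes")
    lengths = {np.asarray(p).shape for p in passes}
    if len(lengths) > 1:
        raise ValueError(f"probability vectors have mismatched shapes: {sorted(lengths)}")
    mean = np.mean([np.asarray(p, dtype=np.float64) for p in passes], axis=0)
    mean = mean / mean.sum()
    n = mean.size
    nz = mean[mean > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return min(1.0, entropy / np.log(n))


def compare_uncertainty_distributions(correct, incorrect,
                                      alternative: str = "two-sided"):
    """Mann-Whitney U rank test between two score samples.

    Returns ``(U, p)`` for the ``correct`` sample against ``incorrect``; used
    to test whether wrong predictions carry systematically higher uncertainty.
    """
    correct = np.asarray(correct, dtype=np.float64)
    incorrect = np.asarray(incorrect, dtype=np.float64)
    if correct.size == 0 or incorrect.size == 0:
        raise ValueError("both score lists must be non-empty")
    res = _stats.mannwhitneyu(correct, incorrect, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
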