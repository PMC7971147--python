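"""Quantitative and visual evaluation against ground truth.

Metrics follow the standard set for these tasks: Jaccard index over all
pixels, pixel accuracy, mean absolute and relative error, pixel-wise Pearson
correlation for image-valued predictions; Jaccard, MAE, MSE, AUC, confusion
matrix and ROC curve for classification. Uncertainty about a metric on a
finite test set is summarized by subsample bootstrapping: the metric's
per-image values are resampled (100 rounds of half the test set, without
replacement within a round) and the distribution of round-medians is
reported.

Figures are rendered to PNG; the numbers behind every figure are always
written as CSV/JSON alongside, so downstream analysis never parses images.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import jaccard_score as _sk_jaccard
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "jaccard_index", "pixel_metrics", "classification_report",
    "bootstrap_metric", "error_map", "evaluate_image_task",
    "evaluate_classification", "UNDEFINED",
]

#: marker for metrics that are undefined on a given input (e.g. Pearson
#: correlation against a constant ground truth)
UNDEFINED = "undefined"

_REL_EPS = 1e-8


def _check_binary_pair(prediction, truth):
    p = np.asarray(prediction)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.astype(bool) if p.dtype == bool else p > 0.5
    t = t.astype(bool) if t.dtype == bool else t > 0.5
    return p, t


def jaccard_index(prediction, truth) -> float:
    """Intersection over union of the foreground pixel sets.

    Both-empty is perfect agreement on absence: defined as 1.0.
    """
    p, t = _check_binary_pair(prediction, truth)
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def pixel_metrics(prediction, truth) -> dict:
    """Accuracy, MAE, mean relative error and Pearson r over all pixels.

    ``accuracy`` is the fraction of agreeing pixels after binarizing at 0.5
    (meaningful for binary arrays). Pearson r against a constant truth is
    reported as :data:`UNDEFINED` rather than NaN.
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pf, tf = p.ravel(), t.ravel()
    out = {
        "accuracy": float(np.mean((pf > 0.5) == (tf > 0.5))),
        "mean_absolute_error": float(np.mean(np.abs(pf - tf))),
        "mean_relative_error": float(np.mean(np.abs(pf - tf) / (np.abs(tf) + _REL_EPS))),
    }
    if np.ptp(tf) == 0 or np.ptp(pf) == 0:
        out["pearson_r"] = UNDEFINED
    else:
        out["pearson_r"] = float(np.corrcoef(pf, tf)[0, 1])
    return out


def classification_report(probabilities, truths, n_classes: int | None = None) -> dict:
    """Error scores, confusion matrix and ROC for a classified test set.

    ``probabilities`` is (n_samples, n_classes); AUC is computed directly for
    the binary case and macro-averaged one-vs-rest for multi-class. MAE/MSE
    are taken on the class indices, matching the convention of reporting them
    alongside the confusion matrix for label predictions.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(truths, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != y.shape[0]:
        raise ValueError("probabilities must be (n_samples, n_classes) matching truths")
    if probs.shape[0] == 0:
        raise ValueError("empty classification input")
    n_classes = n_classes or probs.shape[1]
    pred = probs.argmax(axis=1)
    labels = np.arange(n_classes)
    cm = _sk_confusion(y, pred, labels=labels)
    average = "binary" if n_classes == 2 else "macro"
    out = {
        "jaccard": float(_sk_jaccard(y, pred, labels=labels, average=average,
                                     zero_division=0)),
        "mae": float(np.mean(np.abs(pred - y))),
        "mse": float(np.mean((pred - y) ** 2)),
        "confusion_matrix": cm,
        "accuracy": float(np.mean(pred == y)),
    }
    if n_classes == 2:
        if len(np.unique(y)) < 2:
            out["auc"] = UNDEFINED
            out["roc_points"] = None
        else:
            fpr, tpr, thr = roc_curve(y, probs[:, 1])
            out["auc"] = float(_sk_auc(fpr, tpr))
            out["roc_points"] = np.column_stack([fpr, tpr])
    else:
        try:
            out["auc"] = float(roc_auc_score(y, probs, multi_class="ovr",
                                             average="macro", labels=labels))
        except ValueError:
            out["auc"] = UNDEFINED
        out["roc_points"] = None
    return out


def bootstrap_metric(per_image_values, n_rounds: int = 100, fraction: float = 0.5,
                     seed: int = 0) -> dict:
    """Subsample bootstrap of a per-image metric.

    Each round draws ``ceil(fraction * n)`` values without replacement and
    records their median; reported are the round-medians with their median
    and 25/75 percentiles.
    """
    values = np.asarray(per_image_values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("per-image value list must be non-empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    k = math.ceil(fraction * values.size)
    medians = np.array([np.median(rng.choice(values, size=k, replace=False))
                        for _ in range(n_rounds)])
    return {
        "round_medians": medians,
        "median": float(np.median(medians)),
        "p25": float(np.percentile(medians, 25)),
        "p75": float(np.percentile(medians, 75)),
    }


def error_map(prediction, truth) -> np.ndarray:
    """Signed ternary map: +1 over-predicted, -1 under-predicted, 0 agree."""
    p, t = _check_binary_pair(prediction, truth)
    return p.astype(np.int8) - t.astype(np.int8)


# ---------------------------------------------------------------------------
# report generation


def _use_agg():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _aggregate(df: pd.DataFrame) -> dict:
    agg = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if len(vals):
            agg[col] = {"median": float(vals.median()),
                        "p25": float(vals.quantile(0.25)),
                        "p75": float(vals.quantile(0.75))}
    return agg


def evaluate_image_task(pairs, predictions: dict, outdir, task: str,
                        seed: int = 0, n_bootstrap: int = 100,
                        make_figures: bool = True) -> dict:
    """Evaluate image-valued predictions against ground truth.

    ``predictions`` maps identifier -> continuous prediction array (values in
    [0, 1]). Segmentation metrics are computed on the binarized (0.5)
    prediction; regression metrics on the continuous one. Writes
    ``metrics_per_image.csv``, ``metrics_summary.json`` and
    ``bootstrap_<metric>.csv`` plus figures under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segment = task in ("semantic_segmentation", "instance_segmentation")
    rows = []
    examples = []
    for pair in pairs:
        pred = predictions.get(pair.identifier)
        if pred is None:
            continue
        truth = np.asarray(pair.label, dtype=np.float64)
        pred = np.asarray(pred, dtype=np.float64)
        row = {"filename": pair.identifier}
        if segment:
            binary = pred > 0.5
            tbin = truth > 0.5
            row["jaccard"] = jaccard_index(binary, tbin)
            row.update(pixel_metrics(binary.astype(float), tbin.astype(float)))
        else:
            row.update(pixel_metrics(pred, truth))
        rows.append(row)
        if len(examples) < 3:
            examples.append((pair, pred))
    if not rows:
        raise ValueError("no predictions matched the ground-truth pairs")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "metrics_per_image.csv", index=False)

    summary = {"n_images": len(df), "aggregate": _aggregate(df.drop(columns="filename"))}
    boot_cols = ["jaccard"] if segment else ["pearson_r", "mean_absolute_error"]
    summary["bootstrap"] = {}
    for col in boot_cols:
        if col not in df:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna().to_numpy()
        if vals.size == 0:
            continue
        boot = bootstrap_metric(vals, n_rounds=n_bootstrap, seed=seed)
        pd.DataFrame({"round_median": boot["round_medians"]}).to_csv(
            outdir / f"bootstrap_{col}.csv", index=False)
        summary["bootstrap"][col] = {k: boot[k] for k in ("median", "p25", "p75")}
    (outdir / "metrics_summary.json").write_text(json.dumps(summary, indent=2))

    if make_figures:
        plt = _use_agg()
        # side-by-side panels + error maps for a few examples
        for pair, pred in examples:
            img = np.asarray(pair.image)
            img2d = img if img.ndim == 2 else (img[..., 0] if img.shape[-1] <= 4
                                               else img[0])
            pred2d = pred if pred.ndim == 2 else pred[0]
            truth = np.asarray(pair.label, dtype=np.float64)
            truth2d = truth if truth.ndim == 2 else truth[0]
            ncols = 4 if segment else 3
            fig, axes = plt.subplots(1, ncols, figsize=(3 * ncols, 3))
            for ax, (data, title) in zip(axes, [
                    (img2d, "image"), (truth2d, "groundtruth"), (pred2d, "prediction")]):
                ax.imshow(data, cmap="gray")
                ax.set_title(title)
                ax.axis("off")
            if segment:
                emap = error_map(pred2d > 0.5, truth2d > 0.5)
                axes[3].imshow(emap, cmap="coolwarm", vmin=-1, vmax=1)
                axes[3].set_title("error map")
                axes[3].axis("off")
            fig.tight_layout()
            fig.savefig(outdir / f"panel_{Path(pair.identifier).stem}.png", dpi=90)
            plt.close(fig)
        # metric boxplot
        numeric = df.drop(columns="filename").apply(pd.to_numeric, errors="coerce")
        fig, ax = plt.subplots(figsize=(1.2 * len(numeric.columns) + 2, 3.5))
        numeric.boxplot(ax=ax)
        ax.set_ylabel("metric value")
        fig.tight_layout()
        fig.savefig(outdir / "metrics_boxplot.png", dpi=90)
        plt.close(fig)
    return summary


def evaluate_classification(probabilities, truths, class_names, outdir,
                            identifiers=None, make_figures: bool = True) -> dict:
    """Classification evaluation with confusion matrix and ROC rendering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = classification_report(probabilities, truths, n_classes=len(class_names))
    cm = report["confusion_matrix"]
    pd.DataFrame(cm, index=class_names, columns=class_names).to_csv(
        outdir / "confusion_matrix.csv")
    summary = {k: v for k, v in report.items()
               if k not in ("confusion_matrix", "roc_points")}
    summary["confusion_matrix"] = cm.tolist()
    (outdir / "metrics_summary.json").write_text(json.dumps(summary, indent=2))
    if report["roc_points"] is not None:
        pd.DataFrame(report["roc_points"], columns=["fpr", "tpr"]).to_csv(
            outdir / "roc_points.csv", index=False)
    if make_figures:
        plt = _use_agg()
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(class_names)), class_names, rotation=45)
        ax.set_yticks(range(len(class_names)), class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, str(cm[i, j]), ha="center", va="center")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(outdir / "confusion_matrix.png", dpi=90)
        plt.close(fig)
        if report["roc_points"] is not None:
            fig, ax = plt.subplots(figsize=(4, 3.5))
            ax.plot(report["roc_points"][:, 0], report["roc_points"][:, 1],
                    label=f"AUC = {report['auc']:.3f}")
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.legend()
            fig.tight_layout()
            fig.savefig(outdir / "roc_curve.png", dpi=90)
            plt.close(fig)
    return summary
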