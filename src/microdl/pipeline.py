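"""End-to-end orchestration: load -> split -> train -> predict -> evaluate.

One call to :func:`run_pipeline` executes the full workflow for the configured
task and writes every artifact under the project directory::

    <path>/logs/         run.log, training_log.csv, best_model.npz
    <path>/results/      predictions (+ results.csv, uncertainty maps)
    <path>/evaluation/   metrics tables, bootstrap distributions, figures

Every random stream derives from the config seed, so identical config + seed
reproduces the identical validation split, batch order and augmentations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import uncertainty as unc
from .config import ConfigError, PipelineConfig, seed_everything
from .data import (DataError, DatasetSplit, SamplePair, discover_pairs,
                   load_pair, normalize_image, read_labels_csv, resize_pair,
                   split_validation)
from .evaluate import evaluate_classification, evaluate_image_task
from .instances import detect_and_segment_instances, instances_to_label_map
from .models import build_classifier, build_unet, load_matching_weights
from .training import _to_input, train_model

__all__ = ["RunLog", "run_pipeline", "load_task_data", "evaluate_only"]

_IMAGE_TASKS = ("semantic_segmentation", "instance_segmentation", "regression")


@dataclass
class RunLog:
    """Everything a run did: config echo, training curve, file inventory."""

    config: dict
    seed: int
    weight_report: str = ""
    epochs_run: int = 0
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("nan")
    batch_order: list = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    uncertainty: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    logfile: str = ""

    def write(self, path) -> None:
        """Plain-text log with a machine-readable JSON footer."""
        path = Path(path)
        lines = ["# pipeline run log", "", "## configuration"]
        lines += [f"  {k}: {v}" for k, v in self.config.items()]
        lines += ["", f"seed: {self.seed}", "", "## transfer learning"]
        lines += [self.weight_report or "  no pretrained weights loaded"]
        lines += ["", "## training"]
        for i, (tr, vl) in enumerate(zip(self.train_losses, self.val_losses), 1):
            lines.append(f"  epoch {i}: train={tr:.6f} val={vl:.6f}")
        lines += [f"  best epoch: {self.best_epoch} "
                  f"(val loss {self.best_val_loss:.6f})", "", "## outputs"]
        lines += [f"  {p}" for p in self.outputs]
        footer = {
            "seed": self.seed, "epochs_run": self.epochs_run,
            "best_epoch": self.best_epoch, "best_val_loss": self.best_val_loss,
            "train_losses": self.train_losses, "val_losses": self.val_losses,
            "batch_order": self.batch_order, "outputs": self.outputs,
            "uncertainty": self.uncertainty, "evaluation": self.evaluation,
        }
        lines += ["", "## json", json.dumps(footer)]
        path.write_text("\n".join(lines))
        self.logfile = str(path)


def _prepare_pair(pair: SamplePair, task: str, resize) -> SamplePair:
    image = normalize_image(pair.image)
    label = pair.label
    if isinstance(label, np.ndarray):
        if task in ("semantic_segmentation", "instance_segmentation"):
            label = (label > label.max() / 2 if label.max() > 0
                     else label > 0).astype(np.float32)
        else:
            label = label.astype(np.float32)
            if label.max() > 1.0:
                label = label / label.max()
    out = SamplePair(pair.identifier, image, label)
    if resize is not None:
        out = resize_pair(out, resize)
    return out


def _expand_slices(pairs: list[SamplePair]) -> list[SamplePair]:
    """Split (Z, H, W[, C]) training stacks into per-slice 2D samples."""
    out = []
    for p in pairs:
        img = p.image
        is_stack = img.ndim == 4 or (img.ndim == 3 and img.shape[-1] > 4)
        if not is_stack:
            out.append(p)
            continue
        for z in range(img.shape[0]):
            lbl = p.label[z] if isinstance(p.label, np.ndarray) else p.label
            out.append(SamplePair(f"{p.identifier}#z{z}", img[z], lbl))
    return out


def load_task_data(config: PipelineConfig, split: str) -> list[SamplePair]:
    """Discover, read and normalize all pairs of one split folder."""
    folder = Path(config.data_path) / split
    if config.task == "classification":
        ids = discover_pairs(folder, "class")
        labels = read_labels_csv(folder / "groundtruth" / "labels.csv")
        class_names = sorted(set(labels.values()))
        pairs = [load_pair(folder, i, "class",
                           class_index=class_names.index(labels[i])) for i in ids]
    else:
        ids = discover_pairs(folder, "image")
        pairs = [load_pair(folder, i, "image") for i in ids]
    return [_prepare_pair(p, config.task, config.resize) for p in pairs]


def _class_names(config: PipelineConfig, split: str = "train") -> list[str]:
    labels = read_labels_csv(Path(config.data_path) / split / "groundtruth"
                             / "labels.csv")
    return sorted(set(labels.values()))


def _input_channels(pair: SamplePair) -> int:
    img = pair.image
    if img.ndim == 2 or (img.ndim == 3 and img.shape[-1] > 4):
        return 1
    return img.shape[-1]


def build_task_model(config: PipelineConfig, in_channels: int,
                     rng: np.random.Generator, classifier_layout: str = "lite"):
    """The default network for a task, sized for CPU training."""
    if config.task == "classification":
        return build_classifier(config.n_classes, in_channels=in_channels,
                                layout=classifier_layout, rng=rng)
    head = "linear" if config.task == "regression" else "sigmoid"
    return build_unet(in_channels=in_channels, head=head, rng=rng)


def run_pipeline(config: PipelineConfig, log=print,
                 mc_passes: int = unc.DEFAULT_MC_PASSES) -> RunLog:
    """Execute the full pipeline for one configuration.

    Steps: (i) model initialisation (optionally from pretrained weights),
    (ii) data import, normalization, 20% validation split, shuffling and
    online augmentation, (iii) Adam training with early stopping and
    best-model checkpointing, (iv) prediction on the test set, (v) optional
    Monte-Carlo-dropout uncertainty, then optional automated evaluation.
    Returns the :class:`RunLog`, also written to ``<path>/logs/run.log``.
    """
    rng = seed_everything(config.seed)
    base = Path(config.data_path)
    runlog = RunLog(config=config.to_dict(), seed=config.seed)

    # (ii) data
    train_pairs = load_task_data(config, "train")
    test_pairs = load_task_data(config, "test")
    if config.task == "classification":
        class_names = _class_names(config)
        if len(class_names) != config.n_classes:
            raise ConfigError(
                f"labels.csv defines {len(class_names)} classes "
                f"{class_names} but n_classes={config.n_classes}")
    else:
        class_names = None
        train_pairs = _expand_slices(train_pairs)
    splits = split_validation(train_pairs, fraction=0.2, seed=config.seed)
    splits.test = test_pairs
    log(f"data: {len(splits.train)} train / {len(splits.validation)} validation "
        f"/ {len(test_pairs)} test samples")

    # (i) model init
    model = build_task_model(config, _input_channels(splits.train[0]), rng)
    if config.pretrained_weights_path:
        manifest = load_matching_weights(model, config.pretrained_weights_path)
        runlog.weight_report = manifest.summary()
        log(runlog.weight_report)

    # (iii) training
    state = train_model(model, splits, config, workdir=base, log=log)
    runlog.epochs_run = state.epochs_run
    runlog.train_losses = state.train_losses
    runlog.val_losses = state.val_losses
    runlog.best_epoch = state.best_epoch
    runlog.best_val_loss = state.best_val_loss
    runlog.batch_order = state.batch_order
    runlog.outputs.append(str(state.checkpoint_path))
    runlog.outputs.append(str(base / "logs" / "training_log.csv"))

    # (iv) prediction
    results_dir = base / "results"
    predictions = unc.predict_test_set(model, test_pairs, config.task,
                                       results_dir, class_names=class_names,
                                       log=log)
    for name in predictions:
        if config.task in _IMAGE_TASKS:
            runlog.outputs.append(str(results_dir / f"pred_{Path(name).stem}.tif"))
    if config.task == "classification":
        runlog.outputs.append(str(results_dir / "results.csv"))

    if config.task == "instance_segmentation":
        for pair in test_pairs:
            if pair.identifier not in predictions:
                continue
            inst = detect_and_segment_instances(model, _to_input(pair.image))
            lmap = instances_to_label_map(inst, pair.image.shape[:2]
                                          if pair.image.ndim == 2
                                          else pair.image.shape[-2:])
            out = results_dir / f"instances_{Path(pair.identifier).stem}.tif"
            tifffile.imwrite(out, lmap)
            runlog.outputs.append(str(out))

    # (v) uncertainty
    if config.compute_uncertainty:
        runlog.uncertainty = _run_uncertainty(model, test_pairs, config,
                                              results_dir, runlog, T=mc_passes)

    # evaluation
    if config.auto_evaluate:
        eval_dir = base / "evaluation"
        if config.task == "classification":
            probs = np.stack([predictions[p.identifier] for p in test_pairs
                              if p.identifier in predictions])
            truths = [int(p.label) for p in test_pairs
                      if p.identifier in predictions]
            runlog.evaluation = evaluate_classification(
                probs, truths, class_names, eval_dir)
        else:
            runlog.evaluation = evaluate_image_task(
                test_pairs, predictions, eval_dir, config.task, seed=config.seed)
        runlog.outputs.append(str(eval_dir / "metrics_summary.json"))

    logdir = base / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    runlog.write(logdir / "run.log")
    return runlog


def _run_uncertainty(model, test_pairs, config, results_dir, runlog,
                     T: int) -> dict:
    """Monte-Carlo-dropout pass over the test set; writes maps / score column."""
    from .config import derive_rng
    mc_rng = derive_rng(config.seed, "mc-dropout")
    summary: dict = {"T": T, "per_image": {}}
    if config.task == "classification":
        scores = {}
        for pair in test_pairs:
            passes = unc.mc_dropout_predict(model, _to_input(pair.image), T=T,
                                            rng=mc_rng)
            scores[pair.identifier] = unc.classification_uncertainty(
                [p for p in passes])
        results_csv = results_dir / "results.csv"
        if results_csv.exists():
            df = pd.read_csv(results_csv)
            df["uncertainty"] = [scores.get(f, np.nan) for f in df["filename"]]
            df.to_csv(results_csv, index=False)
        summary["per_image"] = scores
        return summary
    for pair in test_pairs:
        img = pair.image
        if img.ndim == 3 and img.shape[-1] > 4 or img.ndim == 4:
            slice_maps, us = [], []
            for sl in img:
                passes = unc.mc_dropout_predict(model, _to_input(sl), T=T,
                                                rng=mc_rng)
                umap, u = unc.pixel_uncertainty([p[0] for p in passes])
                slice_maps.append(umap)
                us.append(u)
            umap, u = np.stack(slice_maps), float(np.mean(us))
        else:
            passes = unc.mc_dropout_predict(model, _to_input(img), T=T, rng=mc_rng)
            umap, u = unc.pixel_uncertainty([p[0] for p in passes])
        out = results_dir / f"uncertainty_{Path(pair.identifier).stem}.tif"
        tifffile.imwrite(out, umap.astype(np.float32))
        runlog.outputs.append(str(out))
        summary["per_image"][pair.identifier] = u
    us = list(summary["per_image"].values())
    summary["mean_average_pixel_uncertainty"] = float(np.mean(us)) if us else None
    pd.DataFrame(sorted(summary["per_image"].items()),
                 columns=["filename", "average_pixel_uncertainty"]).to_csv(
        results_dir / "uncertainty_summary.csv", index=False)
    return summary


def evaluate_only(config: PipelineConfig) -> dict:
    """Re-run the quantitative evaluation from predictions already on disk."""
    base = Path(config.data_path)
    results_dir = base / "results"
    eval_dir = base / "evaluation"
    test_pairs = load_task_data(config, "test")
    if config.task == "classification":
        df = pd.read_csv(results_dir / "results.csv")
        class_names = _class_names(config)
        probs = df[[f"prob_{c}" for c in class_names]].to_numpy()
        byname = {p.identifier: int(p.label) for p in test_pairs}
        truths = [byname[f] for f in df["filename"]]
        return evaluate_classification(probs, truths, class_names, eval_dir)
    from .data import load_image
    predictions = {}
    for pair in test_pairs:
        path = results_dir / f"pred_{Path(pair.identifier).stem}.tif"
        if path.exists():
            predictions[pair.identifier] = load_image(path)
    if not predictions:
        raise DataError(f"no predictions found under {results_dir}")
    return evaluate_image_task(test_pairs, predictions, eval_dir, config.task,
                               seed=config.seed)
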