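"""Pipeline configuration: twelve user-settable parameters, JSON-backed.

Only ``task`` and ``data_path`` are mandatory; every other key has a documented
default, so a run can be configured with two lines of JSON. Key names follow
the conventional config-file snippet of this kind of pipeline
(``use_algorithm``, ``path``, ``batchsize``, ``Iterations_Over_Dataset``)
with clean canonical aliases. Unknown keys are rejected outright — a silently
ignored typo in a config file is how days of training get wasted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PipelineConfig", "ConfigError", "parse_config", "seed_everything",
           "TASKS", "LOSSES"]

TASKS = ("semantic_segmentation", "instance_segmentation", "regression",
         "classification")
LOSSES = ("binary_crossentropy", "categorical_crossentropy", "mse",
          "instance_composite")

#: default loss per task
_TASK_LOSS = {
    "semantic_segmentation": "binary_crossentropy",
    "instance_segmentation": "binary_crossentropy",
    "regression": "mse",
    "classification": "categorical_crossentropy",
}

# canonical name -> accepted aliases (first form is the conventional JSON key)
_ALIASES = {
    "task": ("use_algorithm", "task"),
    "data_path": ("path", "data_path"),
    "pretrained_weights_path": ("pretrained_weights_path",),
    "batch_size": ("batchsize", "batch_size"),
    "epochs": ("Iterations_Over_Dataset", "epochs"),
    "seed": ("seed",),
    "augmentations": ("data_gen_args", "augmentations"),
    "loss": ("loss_function", "loss"),
    "n_classes": ("num_classes", "n_classes"),
    "resize": ("image_size", "resize"),
    "compute_uncertainty": ("calculate_uncertainty", "compute_uncertainty"),
    "auto_evaluate": ("evaluation", "auto_evaluate"),
}
_KEY_TO_CANONICAL = {a: c for c, aliases in _ALIASES.items() for a in aliases}


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """The twelve pipeline parameters.

    Attributes
    ----------
    task : one of ``TASKS``.
    data_path : project directory containing ``train/`` and ``test/``.
    seed : master seed; every random stream in a run derives from it.
    pretrained_weights_path : optional weight archive for transfer learning.
    batch_size, epochs : training schedule (epochs = iterations over dataset).
    augmentations : list of operator names, or mapping name -> parameter
        overrides (see :mod:`microdl.augment`).
    loss : loss function; defaults by task (bce / cce / mse).
    n_classes : number of classes (semantic segmentation is strictly 2-class,
        background vs. foreground).
    resize : optional ``[height, width]`` applied at import.
    compute_uncertainty : run Monte-Carlo-dropout uncertainty after testing.
    auto_evaluate : run quantitative evaluation after testing.
    """

    task: str
    data_path: str
    seed: int = 1
    pretrained_weights_path: str | None = None
    batch_size: int = 1
    epochs: int = 100
    augmentations: dict = field(default_factory=dict)
    loss: str = ""
    n_classes: int = 2
    resize: tuple[int, int] | None = None
    compute_uncertainty: bool = False
    auto_evaluate: bool = True

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigError(
                f"unknown task {self.task!r}; allowed tasks: {', '.join(TASKS)}")
        if not self.loss:
            self.loss = _TASK_LOSS[self.task]
        if self.loss not in LOSSES:
            raise ConfigError(
                f"unknown loss {self.loss!r}; allowed: {', '.join(LOSSES)}")
        if int(self.batch_size) < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if int(self.epochs) < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        self.batch_size = int(self.batch_size)
        self.epochs = int(self.epochs)
        self.seed = int(self.seed)
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.task == "semantic_segmentation" and self.n_classes != 2:
            raise ConfigError(
                "semantic segmentation is two-class (background vs. foreground); "
                f"got n_classes={self.n_classes}")
        if isinstance(self.augmentations, (list, tuple)):
            self.augmentations = {name: {} for name in self.augmentations}
        if not isinstance(self.augmentations, dict):
            raise ConfigError("augmentations must be a list of operator names "
                              "or a mapping name -> parameters")
        from .augment import validate_operator_names
        validate_operator_names(self.augmentations)
        if self.resize is not None:
            rs = tuple(int(v) for v in self.resize)
            if len(rs) != 2 or min(rs) < 1:
                raise ConfigError(f"resize must be [height, width] > 0, got {self.resize}")
            self.resize = rs

    def to_dict(self) -> dict:
        d = {
            "use_algorithm": self.task,
            "path": str(self.data_path),
            "seed": self.seed,
            "pretrained_weights_path": self.pretrained_weights_path,
            "batchsize": self.batch_size,
            "Iterations_Over_Dataset": self.epochs,
            "augmentations": self.augmentations,
            "loss": self.loss,
            "n_classes": self.n_classes,
            "resize": list(self.resize) if self.resize else None,
            "compute_uncertainty": self.compute_uncertainty,
            "auto_evaluate": self.auto_evaluate,
        }
        return d

    def serialize(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _from_dict(raw: dict) -> PipelineConfig:
    kwargs = {}
    for key, value in raw.items():
        canonical = _KEY_TO_CANONICAL.get(key)
        if canonical is None:
            raise ConfigError(
                f"unknown configuration key {key!r}; accepted keys: "
                f"{sorted(_KEY_TO_CANONICAL)}")
        if canonical in kwargs:
            raise ConfigError(f"configuration key {key!r} given twice (alias clash)")
        kwargs[canonical] = value
    for mandatory, jsonkey in (("task", "use_algorithm"), ("data_path", "path")):
        if mandatory not in kwargs:
            raise ConfigError(f"missing mandatory configuration key {jsonkey!r}")
    # drop explicit nulls so dataclass defaults apply
    kwargs = {k: v for k, v in kwargs.items() if v is not None}
    if "loss" not in kwargs:
        kwargs["loss"] = ""
    return PipelineConfig(**kwargs)


def parse_config(path) -> PipelineConfig:
    """Read and validate a JSON configuration file."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"configuration file {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a JSON object")
    return _from_dict(raw)


def parse_config_dict(raw: dict) -> PipelineConfig:
    """Validate an in-memory configuration mapping (same rules as the file)."""
    return _from_dict(dict(raw))


def seed_everything(seed: int) -> np.random.Generator:
    """Seed every random stream the pipeline touches.

    Seeds the stdlib and legacy numpy global generators and returns the master
    :class:`numpy.random.Generator` from which the pipeline derives its
    per-purpose streams (validation split, shuffling, augmentation sampling,
    weight initialisation, dropout sampling).
    """
    seed = int(seed)
    random.seed(seed)
    np.random.seed(seed % (2 ** 32))
    return np.random.default_rng(seed)


def derive_rng(seed: int, *context) -> np.random.Generator:
    """A reproducible generator for one purpose, e.g. ``derive_rng(seed, "split")``.

    Hashing the string context into the seed sequence keeps the streams for
    different purposes (and epochs, and samples) independent of each other.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for c in context:
        if isinstance(c, str):
            entropy.append(sum((i + 1) * b for i, b in enumerate(c.encode())) % (2 ** 31))
        else:
            entropy.append(int(c) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))
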