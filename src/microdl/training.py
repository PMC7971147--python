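"""Loss functions and the training loop.

Training uses Adam, early stopping on the validation loss, and checkpointing
of the best model to ``<workdir>/logs/``. The per-epoch batch composition is a
deterministic function of the run seed, so two runs with the same
configuration reproduce the same batches (and, on the same hardware, the same
loss trajectory).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import augment_pair
from .config import PipelineConfig, derive_rng
from .data import DatasetSplit, SamplePair
from .models import save_weights
from .nn import Adam

__all__ = ["compute_loss", "loss_grad", "TrainState", "TrainingDiverged",
           "train_model"]

_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


def compute_loss(name: str, prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean loss over elements (mse, bce) or over the batch (cce).

    Cross-entropies clip probabilities to ``[1e-7, 1 - 1e-7]``.
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    if name == "mse":
        return float(np.mean((p - t) ** 2))
    if name == "binary_crossentropy":
        p = np.clip(p, _EPS, 1.0 - _EPS)
        return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    if name == "categorical_crossentropy":
        p = np.clip(p, _EPS, 1.0)
        return float(-np.mean(np.sum(t * np.log(p), axis=-1)))
    raise ValueError(f"unsupported loss {name!r}")


def loss_grad(name: str, prediction: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Gradient of :func:`compute_loss` w.r.t. the prediction."""
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if name == "mse":
        g = 2.0 * (p - t) / p.size
    elif name == "binary_crossentropy":
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        g = (-(t / pc) + (1.0 - t) / (1.0 - pc)) / p.size
    elif name == "categorical_crossentropy":
        pc = np.clip(p, _EPS, 1.0)
        g = -(t / pc) / p.shape[0]
    else:
        raise ValueError(f"unsupported loss {name!r}")
    return g.astype(np.float32)


@dataclass
class TrainState:
    """Outcome of a training run."""

    epochs_run: int = 0
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_val_loss: float = float("inf")
    best_epoch: int = -1
    checkpoint_path: Path | None = None
    batch_order: list[list[list[str]]] = field(default_factory=list)
    """Per epoch: the list of batches, each a list of sample identifiers."""


def _to_input(image: np.ndarray) -> np.ndarray:
    """(H, W) or (H, W, C) channels-last sample -> (C, H, W)."""
    if image.ndim == 2:
        return image[None]
    return np.ascontiguousarray(image.transpose(2, 0, 1))


def _batch_arrays(samples: list[SamplePair], task: str, n_classes: int):
    x = np.stack([_to_input(s.image) for s in samples]).astype(np.float32)
    if task == "classification":
        t = np.zeros((len(samples), n_classes), dtype=np.float32)
        for i, s in enumerate(samples):
            t[i, int(s.label)] = 1.0
    else:
        t = np.stack([np.asarray(s.label, dtype=np.float32)[None]
                      for s in samples])
    return x, t


def evaluate_loss(model, samples: list[SamplePair], loss_name: str, task: str,
                  n_classes: int, batch_size: int = 8) -> float:
    """Mean loss over samples, dropout off, weighted by batch size."""
    total, count = 0.0, 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        x, t = _batch_arrays(chunk, task, n_classes)
        pred = model.forward(x, stochastic=False)
        total += compute_loss(loss_name, pred, t) * len(chunk)
        count += len(chunk)
    return total / max(count, 1)


def train_model(model, splits: DatasetSplit, config: PipelineConfig,
                workdir=None, lr: float = 1e-3, patience: int | None = None,
                min_delta: float = 1e-5, log=print) -> TrainState:
    """Train with Adam and early stopping; keep the best checkpoint.

    Stops after ``patience`` epochs without validation-loss improvement
    (default ``max(5, epochs // 10)``); afterwards the model is restored to
    the best epoch's weights. Per-epoch losses go to
    ``<workdir>/logs/training_log.csv``.
    """
    if not splits.train or not splits.validation:
        raise ValueError("training requires non-empty train and validation sets")
    task, n_classes = config.task, config.n_classes
    loss_name = config.loss
    if loss_name == "instance_composite":
        # the reference instance backend is a semantic network
        loss_name = "binary_crossentropy"
    if patience is None:
        patience = max(5, config.epochs // 10)

    workdir = Path(workdir) if workdir is not None else Path(config.data_path)
    logdir = workdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    ckpt_path = logdir / "best_model.npz"

    optimizer = Adam(model.parameters(), lr=lr)
    model.reseed_dropout(derive_rng(config.seed, "dropout-train"))
    state = TrainState(checkpoint_path=ckpt_path)
    best_state = None
    since_best = 0

    csv_path = logdir / "training_log.csv"
    with open(csv_path, "w", newline="") as fh:
        csv.writer(fh).writerow(["epoch", "train_loss", "val_loss"])

    for epoch in range(config.epochs):
        shuffle_rng = derive_rng(config.seed, "shuffle", epoch)
        order = shuffle_rng.permutation(len(splits.train))
        epoch_batches: list[list[str]] = []
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = []
            for j in idx:
                pair = splits.train[j]
                label = pair.label if isinstance(pair.label, np.ndarray) else None
                image, label, _ = augment_pair(config.augmentations, pair.image,
                                               label, config.seed, epoch, int(j))
                batch.append(SamplePair(pair.identifier, image,
                                        label if label is not None else pair.label))
            epoch_batches.append([s.identifier for s in batch])
            x, t = _batch_arrays(batch, task, n_classes)
            pred = model.forward(x, stochastic=True)
            loss = compute_loss(loss_name, pred, t)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch + 1}, "
                    f"batch {len(epoch_batches)} (samples {epoch_batches[-1]})")
            optimizer.zero_grad()
            model.backward(loss_grad(loss_name, pred, t))
            optimizer.step()
            epoch_loss += loss * len(batch)
            n_seen += len(batch)

        train_loss = epoch_loss / n_seen
        val_loss = evaluate_loss(model, splits.validation, loss_name, task, n_classes)
        state.train_losses.append(train_loss)
        state.val_losses.append(val_loss)
        state.batch_order.append(epoch_batches)
        state.epochs_run = epoch + 1
        with open(csv_path, "a", newline="") as fh:
            csv.writer(fh).writerow([epoch + 1, f"{train_loss:.6f}", f"{val_loss:.6f}"])
        log(f"epoch {epoch + 1}/{config.epochs}  train={train_loss:.4f}  "
            f"val={val_loss:.4f}")

        if val_loss < state.best_val_loss - min_delta:
            state.best_val_loss = val_loss
            state.best_epoch = epoch + 1
            best_state = model.state_dict()
            save_weights(model, ckpt_path)
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                log(f"early stopping after epoch {epoch + 1} "
                    f"(best epoch {state.best_epoch})")
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return state
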