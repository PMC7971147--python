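"""Dataset discovery, image I/O, normalization, splitting and prediction output.

Folder layout (fixed contract)::

    <path>/train/image/         input images
    <path>/train/groundtruth/   labels: images with identical filenames, or
                                labels.csv (``filename,label``) for classification
    <path>/test/image/
    <path>/test/groundtruth/

Input and ground-truth images are paired strictly by identical filename
(including the extension, case-sensitive). Supported formats: single- or
multi-page TIFF (8/16/32-bit) and PNG. A multi-page TIFF is read as a
``(Z, H, W[, C])`` stack — page axis is Z, a trailing small axis is channels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from .config import derive_rng

__all__ = [
    "SamplePair", "DatasetSplit", "DataError", "PairingError",
    "discover_pairs", "load_image", "load_pair", "normalize_image",
    "split_validation", "resize_pair", "write_prediction", "read_labels_csv",
]

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")


class DataError(ValueError):
    """Missing or malformed input data."""


class PairingError(DataError):
    """Image/label filename pairing failed."""


@dataclass
class SamplePair:
    """One input image (or stack) together with its label.

    ``label`` is an image-valued array for segmentation/regression or an
    integer class index for classification.
    """

    identifier: str
    image: np.ndarray
    label: np.ndarray | int | None = None


@dataclass
class DatasetSplit:
    train: list[SamplePair] = field(default_factory=list)
    validation: list[SamplePair] = field(default_factory=list)
    test: list[SamplePair] = field(default_factory=list)


def _list_images(folder: Path) -> list[str]:
    return sorted(p.name for p in folder.iterdir()
                  if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS)


def read_labels_csv(path) -> dict[str, str]:
    """Read a ``filename,label`` table (header required)."""
    path = Path(path)
    if not path.is_file():
        raise DataError(f"labels file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                [f.strip() for f in reader.fieldnames[:2]] != ["filename", "label"]:
            raise DataError(f"{path} must have header 'filename,label'")
        return {row["filename"]: row["label"] for row in reader}


def discover_pairs(folder, label_kind: str = "image") -> list[str]:
    """Identifiers present in both the image folder and the label source.

    ``label_kind`` is ``"image"`` (labels are images under ``groundtruth/``)
    or ``"class"`` (labels come from ``groundtruth/labels.csv``). Pairing is
    strict: any image without a label, or label without an image, raises
    :class:`PairingError` naming the offending files.
    """
    folder = Path(folder)
    image_dir = folder / "image"
    if not image_dir.is_dir():
        raise DataError(f"missing image folder: {image_dir}")
    images = _list_images(image_dir)
    if not images:
        raise DataError(f"no images found in {image_dir}")

    if label_kind == "class":
        labels = set(read_labels_csv(folder / "groundtruth" / "labels.csv"))
    elif label_kind == "image":
        gt_dir = folder / "groundtruth"
        if not gt_dir.is_dir():
            raise DataError(f"missing groundtruth folder: {gt_dir}")
        labels = set(_list_images(gt_dir))
    else:
        raise ValueError(f"label_kind must be 'image' or 'class', got {label_kind!r}")

    unlabelled = [n for n in images if n not in labels]
    orphans = sorted(labels - set(images))
    if unlabelled or orphans:
        parts = []
        if unlabelled:
            parts.append(f"images without matching label: {unlabelled}")
        if orphans:
            parts.append(f"labels without matching image: {orphans}")
        raise PairingError(f"{folder}: " + "; ".join(parts))
    return images


def load_image(path) -> np.ndarray:
    """Read a TIFF or PNG as a float32 array, values unscaled.

    Multi-page TIFFs come back as ``(Z, H, W[, C])``.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(arr, dtype=np.float32)


def load_pair(folder, identifier: str, label_kind: str = "image",
              class_index: int | None = None) -> SamplePair:
    folder = Path(folder)
    image = load_image(folder / "image" / identifier)
    if label_kind == "image":
        label = load_image(folder / "groundtruth" / identifier)
    else:
        label = class_index
    return SamplePair(identifier, image, label)


def normalize_image(image: np.ndarray, mode: str = "minmax",
                    divisor: float | None = None) -> np.ndarray:
    """Scale intensities to [0, 1].

    ``minmax`` (default): per-image min-max scaling — robust to heterogeneous
    acquisition ranges; a constant image maps to all-zeros. ``fixed``: divide
    by ``divisor`` (e.g. the dtype maximum) for intensity-comparable studies.
    """
    image = np.asarray(image, dtype=np.float32)
    if mode == "fixed":
        if not divisor or divisor <= 0:
            raise ValueError("fixed normalization needs a positive divisor")
        return np.clip(image / divisor, 0.0, 1.0)
    if mode != "minmax":
        raise ValueError(f"unknown normalization mode {mode!r}")
    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def split_validation(pairs: list[SamplePair], fraction: float = 0.2,
                     seed: int = 0) -> DatasetSplit:
    """Hold out a seeded random validation fraction from the training pairs.

    ``|validation| = max(1, round(fraction * n))``, so early stopping always
    has something to monitor. Membership depends only on the identifiers,
    the fraction and the seed — not on the order the pairs arrive in. The
    remaining training pairs come back shuffled.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(pairs) < 2:
        raise DataError(
            f"need at least 2 training samples to hold out validation, got {len(pairs)}")
    ordered = sorted(pairs, key=lambda p: p.identifier)
    rng = derive_rng(seed, "validation-split")
    perm = rng.permutation(len(ordered))
    n_val = max(1, round(fraction * len(ordered)))
    val_idx = set(perm[:n_val].tolist())
    validation = [ordered[i] for i in sorted(val_idx)]
    train = [ordered[i] for i in perm[n_val:]]
    return DatasetSplit(train=train, validation=validation)


def _is_binary(arr: np.ndarray) -> bool:
    return bool(np.isin(np.unique(arr), (0, 1)).all())


def _resize_array(arr: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    """Resize the trailing spatial axes H, W of a 2D image or 3D stack."""
    if arr.ndim == 2:
        shape = target
    elif arr.ndim == 3 and arr.shape[-1] <= 4:          # (H, W, C)
        shape = (*target, arr.shape[-1])
    elif arr.ndim == 3:                                  # (Z, H, W)
        shape = (arr.shape[0], *target)
    else:                                                # (Z, H, W, C)
        shape = (arr.shape[0], *target, arr.shape[-1])
    out = _sk_resize(arr.astype(np.float32), shape, order=order,
                     mode="reflect", anti_aliasing=(order > 0), preserve_range=True)
    return out.astype(np.float32)


def resize_pair(pair: SamplePair, target: tuple[int, int]) -> SamplePair:
    """Resize image (smooth) and image-valued label (nearest for binary masks)."""
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be positive, got {target}")
    image = _resize_array(pair.image, (th, tw), order=1)
    label = pair.label
    if isinstance(label, np.ndarray):
        order = 0 if _is_binary(label) else 1
        label = _resize_array(label, (th, tw), order=order)
    return SamplePair(pair.identifier, image, label)


def write_prediction(identifier: str, prediction: np.ndarray, outdir) -> Path:
    """Save a prediction as TIFF (multi-page for 3D) under the input's basename.

    Binary masks go to disk as 8-bit {0, 255}; continuous outputs as 32-bit
    float. Returns the written path.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {outdir}: {exc}") from exc
    prediction = np.asarray(prediction)
    if prediction.dtype == bool or _is_binary(prediction):
        data = (prediction.astype(np.uint8) * 255)
    else:
        data = prediction.astype(np.float32)
    path = outdir / (Path(identifier).stem + ".tif")
    try:
        tifffile.imwrite(path, data)
    except OSError as exc:
        raise DataError(f"cannot write prediction {path}: {exc}") from exc
    return path
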