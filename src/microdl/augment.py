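"""Seeded online augmentation, applied per sample at load time.

Spatial operators (horizontal/vertical flip, zoom, rotation) transform image
and image-valued label with the *identical* geometric map; color operators
(contrast, brightness, poisson noise, feature scaling, mean/std
normalization, resampling, gamma shift) touch the image only. Masks are
interpolated nearest-neighbour so they stay strictly binary; images use
bilinear interpolation with reflect padding.

Every transform is sampled from a generator derived from
``(seed, epoch, sample_index)``, so the full augmentation stream of a run is
reproducible, and each concrete transform is a plain serializable dict that
can be logged or re-applied for visual inspection.

Default parameter ranges are conservative so labels stay valid: flips p=0.5,
rotation uniform in ±20°, zoom in [0.9, 1.1], additive brightness ±0.1,
contrast factor [0.8, 1.25], gamma [0.7, 1.4], poisson photon scale 255,
resampling down-up factor [1, 2]. All overridable via the config's
``augmentations`` mapping.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import rescale as _sk_rescale
from skimage.transform import rotate as _sk_rotate

from .config import ConfigError, derive_rng

__all__ = [
    "SPATIAL_OPERATORS", "COLOR_OPERATORS", "ALL_OPERATORS", "DEFAULT_PARAMS",
    "sample_transform", "apply_spatial", "apply_color", "apply_transform",
    "augment_pair", "validate_operator_names", "save_augmented_examples",
]

SPATIAL_OPERATORS = ("horizontal_flip", "vertical_flip", "zoom", "rotation")
COLOR_OPERATORS = ("contrast", "brightness", "poisson_noise", "feature_scaling",
                   "mean_std_normalization", "resampling", "gamma_shift")
ALL_OPERATORS = SPATIAL_OPERATORS + COLOR_OPERATORS

DEFAULT_PARAMS: dict[str, dict] = {
    "horizontal_flip": {"p": 0.5},
    "vertical_flip": {"p": 0.5},
    "rotation": {"p": 0.5, "range": (-20.0, 20.0)},
    "zoom": {"p": 0.5, "range": (0.9, 1.1)},
    "brightness": {"p": 0.5, "range": (-0.1, 0.1)},
    "contrast": {"p": 0.5, "range": (0.8, 1.25)},
    "gamma_shift": {"p": 0.5, "range": (0.7, 1.4)},
    "poisson_noise": {"p": 0.5, "scale": 255.0},
    "feature_scaling": {"p": 0.5},
    "mean_std_normalization": {"p": 0.5},
    "resampling": {"p": 0.5, "range": (1.0, 2.0)},
}


def validate_operator_names(names) -> None:
    unknown = [n for n in names if n not in ALL_OPERATORS]
    if unknown:
        raise ConfigError(
            f"unknown augmentation operator(s) {unknown}; "
            f"allowed: {list(ALL_OPERATORS)}")


def sample_transform(spec: dict[str, dict], rng: np.random.Generator) -> list[dict]:
    """Draw one concrete transform from an augmentation spec.

    ``spec`` maps operator name -> parameter overrides (may be empty). Each
    enabled operator is independently included with its probability, with
    concrete parameters drawn from its range. Returns an ordered list of
    ``{"op": name, ...params}`` dicts — spatial operators first, so geometry
    is settled before intensity changes.
    """
    validate_operator_names(spec)
    transform = []
    for op in ALL_OPERATORS:          # fixed order -> stable rng consumption
        if op not in spec:
            continue
        params = {**DEFAULT_PARAMS[op], **(spec[op] or {})}
        if rng.random() >= params["p"]:
            continue
        step: dict = {"op": op}
        if op in ("rotation",):
            step["angle"] = float(rng.uniform(*params["range"]))
        elif op == "zoom":
            step["factor"] = float(rng.uniform(*params["range"]))
        elif op == "brightness":
            step["offset"] = float(rng.uniform(*params["range"]))
        elif op == "contrast":
            step["factor"] = float(rng.uniform(*params["range"]))
        elif op == "gamma_shift":
            step["gamma"] = float(rng.uniform(*params["range"]))
        elif op == "poisson_noise":
            step["scale"] = float(params["scale"])
            step["noise_seed"] = int(rng.integers(0, 2 ** 31))
        elif op == "resampling":
            step["factor"] = float(rng.uniform(*params["range"]))
        transform.append(step)
    return transform


def _zoom_same_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Rescale then center-crop or reflect-pad back to the original shape."""
    h, w = arr.shape[:2]
    out = _sk_rescale(arr.astype(np.float32), factor, order=order, mode="reflect",
                      channel_axis=2 if arr.ndim == 3 else None,
                      anti_aliasing=False, preserve_range=True)
    oh, ow = out.shape[:2]
    if oh >= h:
        top, left = (oh - h) // 2, (ow - w) // 2
        out = out[top:top + h, left:left + w]
    else:
        ph, pw = h - oh, w - ow
        pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
        pad += [(0, 0)] * (arr.ndim - 2)
        out = np.pad(out, pad, mode="reflect")
    return out.astype(np.float32)


def _apply_geometric(arr: np.ndarray, step: dict, order: int) -> np.ndarray:
    op = step["op"]
    if op == "horizontal_flip":
        return np.ascontiguousarray(arr[:, ::-1])
    if op == "vertical_flip":
        return np.ascontiguousarray(arr[::-1])
    if op == "rotation":
        out = _sk_rotate(arr.astype(np.float32), step["angle"], resize=False,
                         order=order, mode="reflect", preserve_range=True)
        return out.astype(np.float32)
    if op == "zoom":
        return _zoom_same_shape(arr, step["factor"], order)
    raise ValueError(f"not a spatial operator: {op}")


def apply_spatial(transform: list[dict], image: np.ndarray,
                  label: np.ndarray | None):
    """Apply the transform's spatial steps identically to image and label.

    The label (if image-valued) is re-binarized by nearest-neighbour
    interpolation when it is a binary mask; continuous labels are
    interpolated like the image. Output shapes equal input shapes.
    """
    if label is not None and image.shape[:2] != label.shape[:2]:
        raise ValueError(
            f"image and label spatial shapes differ: {image.shape} vs {label.shape}")
    label_is_mask = label is not None and np.isin(np.unique(label), (0, 1)).all()
    for step in transform:
        if step["op"] not in SPATIAL_OPERATORS:
            continue
        image = _apply_geometric(image, step, order=1)
        if label is not None:
            label = _apply_geometric(label, step, order=0 if label_is_mask else 1)
    if label_is_mask:
        label = (label > 0.5).astype(np.float32)
    return image, label


def apply_color(transform: list[dict], image: np.ndarray) -> np.ndarray:
    """Apply the transform's color steps to the image only.

    Output is clipped back to [0, 1] except for ``mean_std_normalization``,
    which z-scores the image (zero mean, unit variance) and deliberately
    leaves that scale.
    """
    zscored = False
    for step in transform:
        op = step["op"]
        if op not in COLOR_OPERATORS:
            continue
        if op == "brightness":
            image = image + step["offset"]
        elif op == "contrast":
            image = (image - image.mean()) * step["factor"] + image.mean()
        elif op == "gamma_shift":
            if step["gamma"] <= 0:
                raise ValueError(f"gamma must be positive, got {step['gamma']}")
            image = np.clip(image, 0.0, 1.0) ** step["gamma"]
        elif op == "poisson_noise":
            scale = step["scale"]
            noise_rng = np.random.default_rng(step["noise_seed"])
            image = noise_rng.poisson(np.clip(image, 0, None) * scale) / scale
        elif op == "feature_scaling":
            lo, hi = float(image.min()), float(image.max())
            image = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        elif op == "mean_std_normalization":
            sd = float(image.std())
            image = (image - image.mean()) / (sd if sd > 0 else 1.0)
            zscored = True
        elif op == "resampling":
            f = step["factor"]
            if f > 1.0:
                down = _sk_rescale(image.astype(np.float32), 1.0 / f, order=1,
                                   mode="reflect", anti_aliasing=True,
                                   channel_axis=2 if image.ndim == 3 else None,
                                   preserve_range=True)
                from skimage.transform import resize as _sk_resize
                image = _sk_resize(down, image.shape, order=1, mode="reflect",
                                   preserve_range=True)
        image = image.astype(np.float32)
    if not zscored:
        image = np.clip(image, 0.0, 1.0)
    return image.astype(np.float32)


def apply_transform(transform: list[dict], image: np.ndarray,
                    label: np.ndarray | None):
    """Spatial steps on (image, label), then color steps on the image."""
    image, label = apply_spatial(transform, image, label)
    image = apply_color(transform, image)
    return image, label


def augment_pair(spec: dict[str, dict], image: np.ndarray,
                 label: np.ndarray | None, seed: int, epoch: int, index: int):
    """Sample and apply the augmentation for one (epoch, sample) slot."""
    if not spec:
        return image, label, []
    rng = derive_rng(seed, "augment", epoch, index)
    transform = sample_transform(spec, rng)
    image, label = apply_transform(transform, image, label)
    return image, label, transform


def save_augmented_examples(spec: dict[str, dict], pairs, outdir, k: int = 4,
                            seed: int = 0) -> list:
    """Write k augmented image/label pairs as TIFF for visual inspection."""
    from .data import write_prediction
    written = []
    for i, pair in enumerate(pairs[:k]):
        image, label, _ = augment_pair(spec, pair.image, pair.label
                                       if isinstance(pair.label, np.ndarray) else None,
                                       seed, 0, i)
        written.append(write_prediction(f"augmented_{i}_{pair.identifier}",
                                        np.clip(image, 0, 1), outdir))
        if label is not None:
            written.append(write_prediction(f"augmented_{i}_label_{pair.identifier}",
                                            label, outdir))
    return written
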