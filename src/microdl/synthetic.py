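"""Synthetic desk-scale datasets with exact ground truth for all four tasks.

The generator emulates fluorescence-microscopy-like scenes: bright roughly
circular objects ("nuclei") on a darker noisy background. Ground truth is
exact by construction — the binary mask is the analytic union of the planted
blobs, the instance masks are the individual blobs, the regression target is
a deterministic ring ("nuclear envelope") around each blob boundary, and
classification classes differ by planted blob count. Everything is
reproducible from ``(params, seed)`` and written in the pipeline's folder
layout, so every stage up to the end-to-end run is testable without any
download.

Default scene: 64x64 images, 1-6 blobs of radius 4-9 px, foreground mean
0.8, background 0.2, Gaussian noise sd 0.08 — separable enough for the
default CPU-scale networks to learn in minutes, noisy enough not to be
trivial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import distance_transform_edt, gaussian_filter

__all__ = [
    "BlobSceneParams", "generate_scene", "ring_target",
    "generate_segmentation_dataset", "generate_regression_dataset",
    "generate_classification_dataset", "corrupt_images", "write_dataset",
]


@dataclass
class BlobSceneParams:
    """Parameters of one synthetic blob scene."""

    image_size: int = 64
    n_blobs: tuple[int, int] = (1, 6)         #: inclusive count range
    radius: tuple[float, float] = (4.0, 9.0)  #: blob radius range, px
    foreground_mean: float = 0.8
    background_mean: float = 0.2
    noise_sd: float = 0.08
    allow_overlap: bool = False
    n_slices: int = 1                          #: >1 emits a (Z, H, W) stack
    z_extent: tuple[int, int] = (3, 5)         #: blob thickness in slices (3D)


@dataclass
class Scene:
    image: np.ndarray                     #: noisy input, float32 in [0, 1]
    mask: np.ndarray                      #: binary union of blobs, uint8
    instance_masks: list = field(default_factory=list)
    centers: list = field(default_factory=list)
    radii: list = field(default_factory=list)

    @property
    def n_blobs(self) -> int:
        return len(self.instance_masks)


def _place_blobs(params: BlobSceneParams, rng: np.random.Generator):
    """Sample centers/radii; rejection keeps blobs disjoint unless allowed."""
    lo, hi = params.n_blobs
    target = int(rng.integers(lo, hi + 1))
    size = params.image_size
    centers, radii = [], []
    attempts = 0
    while len(centers) < target and attempts < 200:
        attempts += 1
        r = float(rng.uniform(*params.radius))
        c = rng.uniform(r + 1, size - r - 1, size=2)
        if not params.allow_overlap:
            # gap of 2 px keeps instances separable under 8-connectivity
            if any(np.hypot(*(c - c0)) < r + r0 + 2 for c0, r0 in zip(centers, radii)):
                continue
        centers.append(c)
        radii.append(r)
    return centers, radii


def generate_scene(params: BlobSceneParams, rng: np.random.Generator) -> Scene:
    """Draw one scene: noisy image plus exact binary and instance masks."""
    size = params.image_size
    centers, radii = _place_blobs(params, rng)
    if params.n_slices > 1:
        zc = [float(rng.uniform(1, params.n_slices - 1)) for _ in centers]
        zr = [float(rng.uniform(*params.z_extent)) / 2.0 for _ in centers]
        zz, yy, xx = np.mgrid[0:params.n_slices, 0:size, 0:size]
        instance_masks = [
            ((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / r ** 2
            + ((zz - z) ** 2) / max(z2, 0.5) ** 2 <= 1.0
            for c, r, z, z2 in zip(centers, radii, zc, zr)]
    else:
        yy, xx = np.mgrid[0:size, 0:size]
        instance_masks = [np.hypot(yy - c[0], xx - c[1]) <= r
                          for c, r in zip(centers, radii)]
    mask = np.zeros((params.n_slices, size, size) if params.n_slices > 1
                    else (size, size), dtype=np.uint8)
    for m in instance_masks:
        mask |= m.astype(np.uint8)
    clean = params.background_mean + (params.foreground_mean
                                      - params.background_mean) * mask
    image = clean + rng.normal(0.0, params.noise_sd, size=mask.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return Scene(image=image, mask=mask,
                 instance_masks=[m.astype(bool) for m in instance_masks],
                 centers=[c.tolist() for c in centers], radii=radii)


def ring_target(mask: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Continuous "nuclear envelope" target: a Gaussian ridge on blob borders.

    Computed from the noiseless mask via the Euclidean distance to the
    foreground/background boundary, so the image -> target mapping is
    deterministic and learnable. Values lie in [0, 1], peaking at 1 on the
    boundary.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.float32)
    d_in = distance_transform_edt(mask)
    d_out = distance_transform_edt(~mask)
    dist = np.where(mask, d_in, d_out).astype(np.float64)
    # distance is measured to the nearest pixel across the boundary; shift by
    # half a pixel so the ridge sits on the boundary itself
    dist = np.maximum(dist - 0.5, 0.0)
    return np.exp(-(dist ** 2) / (2.0 * sigma ** 2)).astype(np.float32)


def corrupt_images(images: list[np.ndarray], severity: float,
                   seed: int = 0) -> list[np.ndarray]:
    """Out-of-distribution corruption: blur + contrast inversion + noise.

    ``severity`` in [0, 1] scales all three components; severity 0 returns
    the inputs bitwise unchanged.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {severity}")
    if severity == 0.0:
        return [np.array(img, copy=True) for img in images]
    rng = np.random.default_rng(seed)
    out = []
    for img in images:
        x = np.asarray(img, dtype=np.float32)
        x = gaussian_filter(x, sigma=3.0 * severity)
        x = (1.0 - severity) * x + severity * (1.0 - x)     # partial inversion
        x = x + rng.normal(0.0, 0.3 * severity, size=x.shape)
        out.append(np.clip(x, 0.0, 1.0).astype(np.float32))
    return out


def _save_image(path: Path, arr: np.ndarray, kind: str) -> None:
    if kind == "uint16":
        tifffile.imwrite(path, np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16))
    elif kind == "mask":
        tifffile.imwrite(path, (np.asarray(arr) > 0).astype(np.uint8) * 255)
    else:
        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def write_dataset(outdir, train_items, test_items, label_kind: str = "mask",
                  class_labels: dict | None = None) -> dict:
    """Write items into the pipeline's folder layout and a manifest.json.

    ``*_items`` are ``(name, image, label, meta)`` tuples; ``label_kind`` is
    ``"mask"`` (8-bit binary), ``"float"`` (32-bit continuous) or ``"none"``
    (classification; labels come from ``class_labels[name]``).
    """
    outdir = Path(outdir)
    manifest = {"train": {}, "test": {}}
    for split, items in (("train", train_items), ("test", test_items)):
        img_dir = outdir / split / "image"
        gt_dir = outdir / split / "groundtruth"
        img_dir.mkdir(parents=True, exist_ok=True)
        gt_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, image, label, meta in items:
            _save_image(img_dir / name, image, "uint16")
            if label_kind in ("mask", "float"):
                _save_image(gt_dir / name, label, label_kind)
            else:
                rows.append((name, class_labels[name]))
            manifest[split][name] = meta
        if label_kind == "none":
            lines = ["filename,label"] + [f"{n},{l}" for n, l in rows]
            (gt_dir / "labels.csv").write_text("\n".join(lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_segmentation_dataset(params: BlobSceneParams, n_train: int,
                                  n_test: int, outdir, seed: int = 0) -> dict:
    """Blob images with binary masks; per-image blob counts in the manifest."""
    rng = np.random.default_rng(seed)
    def items(n, offset):
        out = []
        for i in range(n):
            scene = generate_scene(params, rng)
            meta = {"n_blobs": scene.n_blobs, "centers": scene.centers,
                    "radii": scene.radii}
            out.append((f"blob_{offset + i:04d}.tif", scene.image, scene.mask, meta))
        return out
    return write_dataset(outdir, items(n_train, 0), items(n_test, n_train),
                         label_kind="mask")


def generate_regression_dataset(params: BlobSceneParams, n_train: int,
                                n_test: int, outdir, seed: int = 0,
                                ring_sigma: float = 1.5) -> dict:
    """Blob images with continuous ring ("envelope") targets."""
    rng = np.random.default_rng(seed)
    def items(n, offset):
        out = []
        for i in range(n):
            scene = generate_scene(params, rng)
            target = ring_target(scene.mask, sigma=ring_sigma)
            meta = {"n_blobs": scene.n_blobs, "centers": scene.centers,
                    "radii": scene.radii}
            out.append((f"ring_{offset + i:04d}.tif", scene.image, target, meta))
        return out
    return write_dataset(outdir, items(n_train, 0), items(n_test, n_train),
                         label_kind="float")


def generate_classification_dataset(n_per_class: int, separation: float, outdir,
                                    params: BlobSceneParams | None = None,
                                    n_classes: int = 2, n_test_per_class: int | None = None,
                                    seed: int = 0) -> dict:
    """Two-or-more-class image set where classes differ by planted blob count.

    Class k's count range is the base range shifted by ``round(k * separation)``
    blobs; ``separation=0`` makes the class-conditional image distributions
    identical (no classifier can beat chance). Labels go to
    ``groundtruth/labels.csv`` in each split.
    """
    if separation < 0:
        raise ValueError(f"separation must be >= 0, got {separation}")
    if n_classes < 2:
        raise ValueError(f"need at least two classes, got {n_classes}")
    base = params or BlobSceneParams(n_blobs=(1, 3), radius=(3.0, 5.0))
    if n_test_per_class is None:
        n_test_per_class = max(1, round(0.3 * n_per_class))
    rng = np.random.default_rng(seed)

    def items(n_each, offset):
        out, labels = [], {}
        for k in range(n_classes):
            shift = round(k * separation)
            p = BlobSceneParams(**{**base.__dict__,
                                   "n_blobs": (base.n_blobs[0] + shift,
                                               base.n_blobs[1] + shift)})
            for i in range(n_each):
                scene = generate_scene(p, rng)
                name = f"cls{k}_{offset + i:04d}.tif"
                labels[name] = f"class_{k}"
                out.append((name, scene.image, None,
                            {"class": k, "n_blobs": scene.n_blobs}))
        return out, labels

    train_items, train_labels = items(n_per_class, 0)
    test_items, test_labels = items(n_test_per_class, n_per_class)
    manifest = {"train": {}, "test": {}}
    outdir = Path(outdir)
    for split, itms, labels in (("train", train_items, train_labels),
                                ("test", test_items, test_labels)):
        img_dir = outdir / split / "image"
        gt_dir = outdir / split / "groundtruth"
        img_dir.mkdir(parents=True, exist_ok=True)
        gt_dir.mkdir(parents=True, exist_ok=True)
        lines = ["filename,label"]
        for name, image, _, meta in itms:
            _save_image(img_dir / name, image, "uint16")
            lines.append(f"{name},{labels[name]}")
            manifest[split][name] = meta
        (gt_dir / "labels.csv").write_text("\n".join(lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
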