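import json

import numpy as np
import pytest

from microdl.data import load_image
from microdl.instances import masks_from_semantic
from microdl.synthetic import (BlobSceneParams, corrupt_images,
                               generate_classification_dataset,
                               generate_regression_dataset, generate_scene,
                               generate_segmentation_dataset, ring_target)


class TestScene:
    def test_mask_is_exactly_the_blob_union(self):
        scene = generate_scene(BlobSceneParams(), np.random.default_rng(0))
        union = np.zeros_like(scene.mask, dtype=bool)
        for m in scene.instance_masks:
            union |= m
        np.testing.assert_array_equal(scene.mask.astype(bool), union)

    def test_nonoverlapping_instances_are_disjoint_components(self):
        for seed in range(8):
            scene = generate_scene(BlobSceneParams(allow_overlap=False),
                                   np.random.default_rng(seed))
            assert len(masks_from_semantic(scene.mask)) == scene.n_blobs

    def test_zero_blob_scene_is_valid(self):
        scene = generate_scene(BlobSceneParams(n_blobs=(0, 0)),
                               np.random.default_rng(1))
        assert scene.n_blobs == 0
        assert scene.mask.sum() == 0
        assert 0.0 <= scene.image.min() and scene.image.max() <= 1.0

    def test_reproducible_from_seed(self):
        a = generate_scene(BlobSceneParams(), np.random.default_rng(5))
        b = generate_scene(BlobSceneParams(), np.random.default_rng(5))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_3d_scene_stacks_slices(self):
        scene = generate_scene(BlobSceneParams(n_slices=8),
                               np.random.default_rng(2))
        assert scene.image.shape == (8, 64, 64)
        assert scene.mask.shape == (8, 64, 64)


class TestRingTarget:
    def test_values_in_unit_interval_and_deterministic(self):
        scene = generate_scene(BlobSceneParams(), np.random.default_rng(3))
        t1 = ring_target(scene.mask)
        t2 = ring_target(scene.mask)
        np.testing.assert_array_equal(t1, t2)
        assert t1.min() >= 0.0 and t1.max() <= 1.0

    def test_ridge_sits_on_blob_boundaries(self):
        scene = generate_scene(BlobSceneParams(n_blobs=(2, 4)),
                               np.random.default_rng(4))
        target = ring_target(scene.mask)
        mask = scene.mask.astype(bool)
        from scipy.ndimage import binary_dilation, binary_erosion
        boundary_band = binary_dilation(mask, iterations=1) \
            & ~binary_erosion(mask, iterations=1)
        assert target[boundary_band].mean() > 2 * target[~boundary_band].mean()

    def test_empty_mask_gives_zero_target(self):
        assert ring_target(np.zeros((16, 16))).sum() == 0.0


class TestSegmentationDataset:
    def test_layout_and_counts(self, tiny_seg_dataset):
        root, manifest = tiny_seg_dataset
        train = sorted((root / "train" / "image").iterdir())
        gts = sorted((root / "train" / "groundtruth").iterdir())
        assert len(train) == len(gts) == 12
        assert [p.name for p in train] == [p.name for p in gts]
        assert len(manifest["test"]) == 4

    def test_manifest_counts_match_component_counts(self, tiny_seg_dataset):
        root, manifest = tiny_seg_dataset
        for name, meta in manifest["train"].items():
            mask = load_image(root / "train" / "groundtruth" / name) > 0
            assert len(masks_from_semantic(mask.astype(np.uint8))) == meta["n_blobs"]

    def test_foreground_fraction_reasonable(self, tiny_seg_dataset):
        root, manifest = tiny_seg_dataset
        fracs = []
        for name in manifest["train"]:
            mask = load_image(root / "train" / "groundtruth" / name) > 0
            fracs.append(mask.mean())
        assert 0.0 <= min(fracs) and max(fracs) < 0.5


class TestRegressionDataset:
    def test_targets_written_as_float_in_unit_interval(self, tmp_path):
        generate_regression_dataset(BlobSceneParams(image_size=32), 3, 2,
                                    tmp_path, seed=0)
        target = load_image(tmp_path / "train" / "groundtruth" / "ring_0000.tif")
        assert target.dtype == np.float32
        assert 0.0 <= target.min() and target.max() <= 1.0
        assert len(np.unique(target)) > 2    # continuous, not a mask


class TestClassificationDataset:
    def test_counts_and_csv(self, tmp_path):
        manifest = generate_classification_dataset(
            10, separation=4.0, outdir=tmp_path, n_test_per_class=3, seed=0)
        assert len(manifest["train"]) == 20
        csv_text = (tmp_path / "train" / "groundtruth" / "labels.csv").read_text()
        assert csv_text.startswith("filename,label")
        assert len(csv_text.strip().splitlines()) == 21
        assert len(list((tmp_path / "test" / "image").iterdir())) == 6

    def test_large_separation_is_linearly_countable(self, tmp_path):
        # closed-form sanity oracle: with separation 4 the planted count
        # ranges [1,3] and [5,7] do not overlap, so a count threshold
        # classifies perfectly
        manifest = generate_classification_dataset(
            15, separation=4.0, outdir=tmp_path, n_test_per_class=2, seed=1)
        counts = {0: [], 1: []}
        for meta in manifest["train"].values():
            counts[meta["class"]].append(meta["n_blobs"])
        assert max(counts[0]) < min(counts[1])

    def test_zero_separation_gives_identical_count_ranges(self, tmp_path):
        manifest = generate_classification_dataset(
            30, separation=0.0, outdir=tmp_path, n_test_per_class=2, seed=2)
        counts = {0: set(), 1: set()}
        for meta in manifest["train"].values():
            counts[meta["class"]].add(meta["n_blobs"])
        # same generating range for both classes
        assert counts[0] | counts[1] <= {1, 2, 3}

    def test_negative_separation_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_classification_dataset(5, separation=-1.0, outdir=tmp_path)


class TestCorruption:
    def test_severity_zero_is_bitwise_identity(self, rng):
        imgs = [rng.random((16, 16)).astype(np.float32) for _ in range(3)]
        out = corrupt_images(imgs, severity=0.0)
        for a, b in zip(imgs, out):
            np.testing.assert_array_equal(a, b)

    def test_corruption_is_seeded_and_reproducible(self, rng):
        imgs = [rng.random((16, 16)).astype(np.float32)]
        a = corrupt_images(imgs, severity=1.0, seed=4)
        b = corrupt_images(imgs, severity=1.0, seed=4)
        np.testing.assert_array_equal(a[0], b[0])

    def test_full_severity_changes_images_substantially(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        out = corrupt_images([img], severity=1.0, seed=0)[0]
        assert np.abs(out - img).mean() > 0.05
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_severity_rejected(self):
        with pytest.raises(ValueError):
            corrupt_images([np.zeros((4, 4))], severity=1.5)
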