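import numpy as np
import pytest
import tifffile
import imageio.v3 as iio

from microdl.data import (DataError, PairingError, SamplePair, discover_pairs,
                          load_image, normalize_image, resize_pair,
                          split_validation, write_prediction)


def make_folder(tmp_path, images, labels, csv=None):
    (tmp_path / "image").mkdir(parents=True)
    (tmp_path / "groundtruth").mkdir(parents=True)
    for name in images:
        tifffile.imwrite(tmp_path / "image" / name,
                         np.zeros((8, 8), dtype=np.uint8))
    for name in labels:
        tifffile.imwrite(tmp_path / "groundtruth" / name,
                         np.zeros((8, 8), dtype=np.uint8))
    if csv is not None:
        (tmp_path / "groundtruth" / "labels.csv").write_text(csv)
    return tmp_path


class TestDiscovery:
    def test_matching_names_returned_sorted(self, tmp_path):
        folder = make_folder(tmp_path, ["b.tif", "a.tif"], ["a.tif", "b.tif"])
        assert discover_pairs(folder) == ["a.tif", "b.tif"]

    def test_case_sensitive_mismatch_is_a_pairing_error(self, tmp_path):
        folder = make_folder(tmp_path, ["a.tif"], ["A.tif"])
        with pytest.raises(PairingError, match="a.tif"):
            discover_pairs(folder)

    def test_empty_folder_is_a_data_error(self, tmp_path):
        (tmp_path / "image").mkdir()
        with pytest.raises(DataError):
            discover_pairs(tmp_path)

    def test_classification_pairs_against_csv(self, tmp_path):
        folder = make_folder(tmp_path, ["x.tif"], [],
                             csv="filename,label\nx.tif,blast\n")
        assert discover_pairs(folder, "class") == ["x.tif"]

    def test_image_missing_from_csv_is_an_error(self, tmp_path):
        folder = make_folder(tmp_path, ["x.tif", "y.tif"], [],
                             csv="filename,label\nx.tif,blast\n")
        with pytest.raises(PairingError, match="y.tif"):
            discover_pairs(folder, "class")


class TestLoading:
    def test_single_page_16bit_tiff(self, tmp_path):
        path = tmp_path / "a.tif"
        tifffile.imwrite(path, np.arange(64 * 64, dtype=np.uint16).reshape(64, 64))
        arr = load_image(path)
        assert arr.shape == (64, 64)
        assert arr.dtype == np.float32
        assert arr.max() == 64 * 64 - 1  # unscaled

    def test_multi_page_tiff_becomes_stack(self, tmp_path):
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, np.zeros((8, 64, 64), dtype=np.uint8))
        assert load_image(path).shape == (8, 64, 64)

    def test_rgb_png_keeps_channels(self, tmp_path):
        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((32, 32, 3), dtype=np.uint8))
        assert load_image(path).shape == (32, 32, 3)

    def test_unreadable_file_raises_io_error(self, tmp_path):
        path = tmp_path / "broken.tif"
        path.write_bytes(b"not a tiff")
        with pytest.raises(DataError):
            load_image(path)


class TestNormalization:
    def test_uint8_full_range_divides_by_255(self):
        img = np.array([[0, 255], [128, 64]], dtype=np.uint8)
        np.testing.assert_allclose(normalize_image(img), img / 255.0, atol=1e-7)

    def test_constant_image_maps_to_zero(self):
        assert normalize_image(np.full((4, 4), 7.0)).sum() == 0.0

    def test_min_max_formula_on_uint16(self):
        img = np.array([[100, 600], [1100, 350]], dtype=np.uint16)
        np.testing.assert_allclose(normalize_image(img),
                                   (img.astype(float) - 100) / 1000, atol=1e-7)

    def test_fixed_mode_uses_divisor(self):
        img = np.array([[0, 1000]], dtype=np.uint16)
        np.testing.assert_allclose(normalize_image(img, "fixed", 2000),
                                   [[0.0, 0.5]])


class TestSplit:
    @pytest.mark.parametrize("n,expected_val", [(5, 1), (10, 2), (13, 3)])
    def test_twenty_percent_split_sizes(self, n, expected_val):
        pairs = [SamplePair(f"{i}.tif", None) for i in range(n)]
        split = split_validation(pairs, 0.2, seed=0)
        assert len(split.validation) == expected_val
        assert len(split.train) == n - expected_val

    def test_membership_invariant_to_input_ordering(self):
        pairs = [SamplePair(f"{i}.tif", None) for i in range(9)]
        a = split_validation(pairs, 0.2, seed=3)
        b = split_validation(list(reversed(pairs)), 0.2, seed=3)
        assert {p.identifier for p in a.validation} == \
               {p.identifier for p in b.validation}

    def test_train_and_validation_are_disjoint_and_cover(self):
        pairs = [SamplePair(f"{i}.tif", None) for i in range(11)]
        split = split_validation(pairs, 0.2, seed=5)
        train = {p.identifier for p in split.train}
        val = {p.identifier for p in split.validation}
        assert not train & val
        assert train | val == {p.identifier for p in pairs}

    def test_single_sample_cannot_be_split(self):
        with pytest.raises(DataError):
            split_validation([SamplePair("a.tif", None)], 0.2, seed=0)


class TestResize:
    def test_binary_mask_stays_binary_when_downsized(self, rng):
        mask = (rng.random((64, 64)) > 0.5).astype(np.float32)
        pair = resize_pair(SamplePair("m.tif", rng.random((64, 64)), mask),
                           (32, 32))
        assert pair.label.shape == (32, 32)
        assert set(np.unique(pair.label)) <= {0.0, 1.0}

    def test_upsizing_shape(self, rng):
        pair = resize_pair(SamplePair("m.tif", rng.random((64, 64)).astype(np.float32)),
                           (128, 128))
        assert pair.image.shape == (128, 128)

    def test_continuous_label_resized_smoothly(self, rng):
        label = rng.random((64, 64)).astype(np.float32)
        pair = resize_pair(SamplePair("m.tif", rng.random((64, 64)), label),
                           (32, 32))
        # a smooth resize of a continuous field produces intermediate values
        assert len(np.unique(pair.label)) > 2

    def test_class_label_untouched(self, rng):
        pair = resize_pair(SamplePair("m.tif", rng.random((64, 64)), 3), (32, 32))
        assert pair.label == 3


class TestWriting:
    def test_3d_prediction_round_trip(self, tmp_path, rng):
        pred = rng.random((8, 64, 64)).astype(np.float32)
        path = write_prediction("vol.tif", pred, tmp_path)
        back = load_image(path)
        assert back.shape == (8, 64, 64)
        np.testing.assert_allclose(back, pred, atol=1e-6)

    def test_binary_mask_stored_as_0_255(self, tmp_path, rng):
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        path = write_prediction("mask.tif", mask, tmp_path)
        raw = tifffile.imread(path)
        assert raw.dtype == np.uint8
        assert set(np.unique(raw)) <= {0, 255}

    def test_basename_follows_input_identifier(self, tmp_path, rng):
        path = write_prediction("sample_007.png", rng.random((4, 4)), tmp_path)
        assert path.name == "sample_007.tif"
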