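import numpy as np
import pytest

from microdl.synthetic import BlobSceneParams, generate_segmentation_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_seg_dataset(tmp_path_factory):
    """A small on-disk segmentation dataset shared by I/O and pipeline tests."""
    root = tmp_path_factory.mktemp("tiny_seg")
    params = BlobSceneParams(image_size=32, n_blobs=(1, 3), radius=(3.0, 6.0))
    manifest = generate_segmentation_dataset(params, n_train=12, n_test=4,
                                             outdir=root, seed=42)
    return root, manifest
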