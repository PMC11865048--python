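import numpy as np
import pytest

from mungseed import SyntheticSceneSpec, generate_dataset, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def grid_scene():
    """A 3x4 grid scene with 12 seeds plus its ground truth."""
    spec = SyntheticSceneSpec(image_size=(224, 224), grid=(3, 4), n_classes=8)
    image, mask, boxes = generate_scene(spec, class_label=2, n_seeds=12, seed=7)
    return spec, image, mask, boxes


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk crop dataset: 4 classes x 6 images at 32x32."""
    root = tmp_path_factory.mktemp("tinyds")
    spec = SyntheticSceneSpec(image_size=(32, 32), n_classes=4)
    manifest = generate_dataset(spec, [6, 6, 6, 6], root, seed=13)
    return root, manifest
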