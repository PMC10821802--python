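import numpy as np
import pytest

from leafswin.data import class_specs, generate_class_arrays, dataset_manifest
from leafswin.swin import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest geometry-valid config: 8x8 image, one stage, 2x2 windows."""
    return ModelConfig(image_size=8, patch_size=4, embed_dim=8, window_size=2,
                       depths=(2,), num_heads=(2,), num_classes=3, mlp_ratio=2.0)


@pytest.fixture(scope="session")
def smoke_config():
    """Desk-scale two-stage config used for training tests (56 px, C=32)."""
    return ModelConfig(image_size=56, embed_dim=32, depths=(2, 2), num_heads=(2, 4),
                       num_classes=2)


@pytest.fixture(scope="session")
def smoke_dataset():
    """Two visually distinct classes (healthy vs serious), 8 images each, 56 px."""
    specs = class_specs(dataset_manifest())
    two = [specs[0], specs[21]]          # Apple healthy / Peach Bacterial Spot serious
    X, y = generate_class_arrays(two, [8, 8], size=56, seed=7)
    return X, y


def finite_difference(fn, arr, eps=1e-6):
    """Central-difference gradient of scalar ``fn`` w.r.t. every entry of ``arr``."""
    grad = np.zeros_like(arr, dtype=np.float64)
    flat = arr.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        up = fn()
        flat[i] = old - eps
        down = fn()
        flat[i] = old
        gflat[i] = (up - down) / (2.0 * eps)
    return grad
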