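import numpy as np
import pytest

from veinline import CaptureParams, generate_dataset, generate_finger_image, make_finger_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_image(rng):
    """Factory for random uint8 images of a given shape."""

    def make(shape=(64, 192)):
        return rng.integers(0, 256, size=shape, dtype=np.uint8)

    return make


@pytest.fixture(scope="session")
def capture_pair():
    """Two samples of one finger plus one sample of another finger."""
    model_a = make_finger_model(11)
    model_b = make_finger_model(22)
    return (
        generate_finger_image(model_a, 1),
        generate_finger_image(model_a, 2),
        generate_finger_image(model_b, 1),
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """On-disk synthetic dataset: 2 subjects x 2 fingers x 3 samples."""
    root = tmp_path_factory.mktemp("veins")
    index = generate_dataset(2, 2, 3, root_seed=5, out_dir=root)
    return root, index
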