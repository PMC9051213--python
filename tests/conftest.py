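import numpy as np
import pytest

import dendrilearn as dl


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale fixture: 10 classes, 28x28, constant-pixel block included."""
    return dl.SyntheticSpec(
        n_classes=10,
        n_per_class_train=30,
        n_per_class_test=15,
        image_side=28,
        n_constant_pixels=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def desk_raw(desk_spec):
    return dl.gen_images(desk_spec)


@pytest.fixture(scope="session")
def desk_normalized(desk_raw):
    train, test = desk_raw
    return dl.normalize_pair(train, test)


@pytest.fixture(scope="session")
def tiny_normalized():
    """3-class 8x8 set for fast end-to-end runs."""
    spec = dl.SyntheticSpec(
        n_classes=3,
        n_per_class_train=20,
        n_per_class_test=10,
        image_side=8,
        n_constant_pixels=3,
        seed=7,
    )
    train, test = dl.gen_images(spec)
    return dl.normalize_pair(train, test)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
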