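import numpy as np
import pytest

from dualsct import phantom, training


@pytest.fixture(scope="session")
def small_spec():
    return phantom.PhantomSpec(seed=42)


@pytest.fixture(scope="session")
def label_volume(small_spec):
    return phantom.generate_label_volume(small_spec)


@pytest.fixture(scope="session")
def triplet(small_spec):
    """One raw (HU-space) phantom triplet."""
    return phantom.generate_triplet(small_spec)


@pytest.fixture(scope="session")
def norm_triplet(triplet):
    """The same triplet preprocessed to [-1, 1]."""
    return training.preprocess_triplet(triplet)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
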