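import numpy as np
import pytest
from hypothesis import settings

from pulsewave.synthetic import generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """50 periods, 10 per class — enough for classifier and fold tests."""
    return generate_dataset(counts=(10, 10, 10, 10, 10), seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The desk-scale 247-period profile used by the evaluation protocol."""
    return generate_dataset(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
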