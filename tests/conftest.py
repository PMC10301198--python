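import numpy as np
import pytest
from hypothesis import settings

import eagletune as et

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


class ConstantRng:
    """Stand-in random source returning a fixed uniform value."""

    def __init__(self, value: float):
        self.value = value

    def uniform(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """Default 216-day synthetic record shared by read-only tests."""
    return et.generate(et.SyntheticConfig(seed=0))


@pytest.fixture
def linear_space():
    return et.SearchSpace(lower=(-5.0, -5.0), upper=(5.0, 5.0), scale=("linear", "linear"))


@pytest.fixture
def constant_rng():
    return ConstantRng
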