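import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_sample(rng):
    """A generic pair of normal samples with a moderate true difference."""
    return rng.normal(0.5, 1.0, 45), rng.normal(0.0, 1.0, 55)
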