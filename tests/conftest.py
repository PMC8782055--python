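import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sporehit.io import load_beam_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beams():
    """Shipped He/Ar/Fe beam registry with facility exposure parameters."""
    return load_beam_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220116)
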