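import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3_pair():
    """The heterogeneous double-sinusoidal pair used throughout the
    correlation/frequency/time-constant studies."""
    from ousync import make_double_sine
    return make_double_sine(0.1, 0.32), make_double_sine(0.6, 0.30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
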