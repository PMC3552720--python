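import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from cmrperf import PhantomConfig, simulate_subject


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def noise_free_subject(default_config):
    """One rendered subject with zero noise: exact oracle for extraction."""
    return simulate_subject(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
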