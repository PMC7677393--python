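import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_single_variant():
    """8 samples, 4 cases, one het variant carried by the first two samples
    (both cases): the canonical exhaustive-enumeration toy."""
    G = np.zeros((8, 1))
    G[:2, 0] = 1.0
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    return G, y


def standardized_noise(n: int, seed: int = 0) -> np.ndarray:
    """Deterministic vector with exactly zero mean and unit sample SD, for
    building arms with exact means/SDs in classifier tests."""
    z = np.random.default_rng(seed).normal(size=n)
    z = z - z.mean()
    return z / z.std(ddof=1)
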