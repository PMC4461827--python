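import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazekin.fixtures import random_states, random_targets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation from a random rotation vector."""
    from gazekin.rotation import rotation_from_rotvec

    v = rng.normal(size=3)
    v = v / np.linalg.norm(v) * rng.uniform(0.0, np.pi * 0.99)
    return rotation_from_rotvec(v)


@pytest.fixture(scope="session")
def seeded_states():
    return random_states(123, 50)


@pytest.fixture(scope="session")
def seeded_targets():
    return random_targets(321, 50)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
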