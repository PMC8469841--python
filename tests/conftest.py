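import numpy as np
import pytest
from hypothesis import settings

from landmarkrl import ObservationSpec, PhantomConfig, Volume, generate_phantom

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """Random 16^3 volume with anisotropic-friendly metadata."""
    return Volume(
        data=rng.random((16, 16, 16)).astype(np.float32),
        spacing=(0.33, 0.33, 0.33),
        origin=(-5.0, 2.0, 0.0),
    )


@pytest.fixture
def obs_spec():
    return ObservationSpec(n=8, history=3, window=(0.0, 1.0))


@pytest.fixture(scope="session")
def phantom_pair():
    """One noiseless-ish phantom with its landmark (session-cached)."""
    return generate_phantom(PhantomConfig(seed=11))
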