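import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dense_sim():
    """Well-separated dense-texture simulation used across modules."""
    from stormseg import SimParams, generate

    params = SimParams(
        image_size=(384, 384),
        n_nuclei=6,
        radius_range=(10.0, 16.0),
        texture="dense",
        n_noise_regions=0,
        min_separation=70.0,
        seed=42,
    )
    return params, generate(params)


@pytest.fixture(scope="session")
def noisy_sim():
    """Discrete-texture simulation with noise regions."""
    from stormseg import SimParams, generate

    params = SimParams(
        image_size=(384, 384),
        n_nuclei=5,
        radius_range=(10.0, 16.0),
        texture="discrete",
        n_noise_regions=2,
        min_separation=70.0,
        seed=7,
    )
    return params, generate(params)


def make_mask(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


def rect_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m
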