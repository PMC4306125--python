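import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvstrain import phantom as ph

settings.register_profile(
    "repeatable", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_phantom():
    """Default beating-annulus phantom (16 frames, 1% noise)."""
    spec = ph.PhantomSpec()
    cine, truth = ph.generate(spec)
    return spec, cine, truth


@pytest.fixture(scope="session")
def contraction_phantom():
    """Strong contraction (4 px peak endocardial excursion)."""
    spec = ph.PhantomSpec(contraction=4.0 / 12.0, thickening=0.25,
                          noise_sigma=0.01)
    cine, truth = ph.generate(spec)
    return spec, cine, truth


@pytest.fixture(scope="session")
def clean_ring_phantom():
    """Noise-free circular annulus (no texture/ellipticity) for contour
    and edge-location oracles."""
    spec = ph.PhantomSpec(noise_sigma=0.0, ellipticity=0.0, texture=0.0)
    cine, truth = ph.generate(spec)
    return spec, cine, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
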