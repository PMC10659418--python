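import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abersim.optics import OpticalConfig
from abersim.phantom import PhantomConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_optics():
    """32-cube light-sheet configuration for fast PSF tests."""
    return OpticalConfig(shape=(32, 32, 32))


@pytest.fixture(scope="session")
def medium_optics():
    return OpticalConfig(shape=(64, 64, 64))


@pytest.fixture(scope="session")
def sparse_phantom_config():
    """Reduced structure counts for 64-cube phantoms."""
    return PhantomConfig(
        shape=(64, 64, 64), n_dots=5, n_lines=3, n_circles=2,
        n_spheres=2, n_shells=1, seed=7,
    )
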