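import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plimox import (AcquisitionConfig, PhantomConfig, SectioningModel,
                    generate_phantom)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def acq_noiseless():
    """Default-timing acquisition, 8x8 grid, no noise."""
    return AcquisitionConfig(grid_shape=(8, 8), noise_model="none")


@pytest.fixture(scope="session")
def phantom_small():
    """48x48 phantom with a thin capillary bed, seeded."""
    cfg = PhantomConfig(grid_shape=(48, 48), n_capillaries=5)
    return generate_phantom(cfg, seed=7)


@pytest.fixture(scope="session")
def sectioning_wide():
    """Focal plane between plexuses, sigma wide enough that every vessel
    keeps a usable depth-sectioning weight."""
    return SectioningModel(focal_depth=35.0, sectioning_sigma=40.0)


@pytest.fixture(scope="session")
def acq_small_noiseless():
    return AcquisitionConfig(grid_shape=(48, 48), noise_model="none")


def approx_rel(a, b, rtol):
    return np.allclose(a, b, rtol=rtol, atol=0)
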