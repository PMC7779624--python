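import logging

import numpy as np
import pytest

from glymphiron.grids import VolumeGrid
from glymphiron.simulate import PhantomSpec, make_susceptibility_phantom

logging.getLogger("glymphiron").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def nucleus_phantom():
    """Noiseless seven-nucleus phantom without background sources."""
    return make_susceptibility_phantom(
        PhantomSpec(noise_sd=0.0, background_sources=())
    )


@pytest.fixture(scope="session")
def full_phantom():
    """Noiseless phantom with nuclei and outside-mask background sources."""
    return make_susceptibility_phantom(PhantomSpec(noise_sd=0.0))


@pytest.fixture
def unit_grid():
    """Empty 32-cube, 1 mm isotropic, B0 along z."""
    return VolumeGrid(np.zeros((32, 32, 32)))
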