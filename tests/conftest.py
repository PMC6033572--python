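import numpy as np
import pytest

from octsim.focusing import OpticalSystemSpec
from octsim.grid import GridSpec, MaterialMap

LAMBDA0 = 1.3  # um, central vacuum wavelength of the modelled system
C = 0.299792458  # um/fs


@pytest.fixture(scope="session")
def system():
    """The modelled spectral-domain OCT system (Telesto-II-like)."""
    return OpticalSystemSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_1d_grid(nz=420, cell_size=LAMBDA0 / 6, n=1.0, pml=10):
    g = GridSpec(cell_size, (1, 1, nz), pml_thickness=pml, background_index=n)
    return g, MaterialMap.homogeneous(g)
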