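import numpy as np
import pytest

from rodconfine.geometry import Confinement
from rodconfine.fields import Grid2D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def disk():
    """The reference disk chamber: R_outer = 40 D, H = 6 D."""
    return Confinement(40.0, 0.0, 6.0)


@pytest.fixture
def annulus():
    """Annulus chamber with a mid-sized hole."""
    return Confinement(40.0, 12.0, 6.0)


@pytest.fixture
def disk_grid(disk):
    return Grid2D.for_confinement(disk, cell_size=1.0)


@pytest.fixture
def annulus_grid(annulus):
    return Grid2D.for_confinement(annulus, cell_size=1.0)


@pytest.fixture
def small_disk():
    """A small chamber for fast MC tests."""
    return Confinement(12.0, 0.0, 3.0)
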