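import math

import numpy as np
import pytest

from filacol.fixtures import FixtureSpec, make_fixture
from filacol.geometry import Cell, CellTypeParams


@pytest.fixture
def circle_cell():
    """Unit-ish circular cell at the origin (a = b, beta = pi/4)."""
    tp = CellTypeParams("sated", half_length=1.0, half_width=1.0, beta=math.pi / 4)
    return Cell(id=0, centre=np.zeros(2), orientation=0.0, type_params=tp)


@pytest.fixture
def ellipse_cell():
    tp = CellTypeParams("sated", half_length=2.0, half_width=1.0, beta=math.pi / 4)
    return Cell(id=0, centre=np.zeros(2), orientation=0.0, type_params=tp)


@pytest.fixture(scope="session")
def disk_mask():
    return make_fixture(FixtureSpec(kind="disk", radius=100))


@pytest.fixture(scope="session")
def spiked_mask():
    """Disk with 8 radial spikes, exactly 2 inside the counting quadrant."""
    return make_fixture(
        FixtureSpec(kind="disk_spikes", radius=100, n_spikes=8,
                    spike_length=80, spike_width=5)
    )
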