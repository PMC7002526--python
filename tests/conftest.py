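import numpy as np
import pytest

from acoct.beam_optics import BeamGeometry
from acoct.phantom_simulator import Phantom, simulate_bscan


@pytest.fixture(scope="session")
def geometry():
    return BeamGeometry()


@pytest.fixture(scope="session")
def geometry_air():
    return BeamGeometry(refractive_index=1.0)


@pytest.fixture(scope="session")
def two_bead_phantom():
    """One bead at the focus depth, one 200 um (geometric) below it."""
    return Phantom(
        np.array([[0.0, 120.0, 1.0], [0.0, 320.0, 1.0]]),
        extent=((-200.0, 200.0), (0.0, 400.0)),
    )


@pytest.fixture(scope="session")
def focused_stack(two_bead_phantom, geometry):
    return simulate_bscan(two_bead_phantom, geometry, 0.0, n_u=256, n_v=512,
                          focus_depth=120.0, surface_row=30.0, seed=1)


def grid_bead_phantom(seed=0, n=14, extent=((-150.0, 150.0), (0.0, 330.0))):
    """Well-separated beads spread over depth for alignment tests."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(extent[0][0] * 0.6, extent[0][1] * 0.6, n)
    z = np.linspace(40.0, extent[1][1] - 30.0, n) + rng.uniform(-8, 8, n)
    return Phantom(np.column_stack([x, z, np.ones(n)]), extent=extent)
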