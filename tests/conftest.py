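import numpy as np
import pytest

from softwg.geometry import MaterialAssignment, MaterialGrid, Region, TubeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20180914)


@pytest.fixture
def materials():
    return MaterialAssignment()


@pytest.fixture
def small_geometry():
    """A reduced tube that still resolves the shell at 2 mm cells."""
    return TubeGeometry(inner_diameter_mm=12.0, outer_diameter_mm=28.0, internode_length_mm=40.0)


def uniform_grid(dims, dx, eps_r=1.0, sigma=0.0, axis=2):
    shape = tuple(dims)
    return MaterialGrid(
        eps_r=np.full(shape, float(eps_r)),
        sigma=np.full(shape, float(sigma)),
        labels=np.full(shape, int(Region.OUTER_SOLUTION), dtype=np.uint8),
        cell_size=dx,
        axis=axis,
    )


@pytest.fixture
def make_uniform_grid():
    return uniform_grid
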