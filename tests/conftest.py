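import numpy as np
import pytest
import trimesh

from mtlmorph import lddmm
from mtlmorph.surface import TriSurface


@pytest.fixture(scope="session")
def unit_cube():
    """12-triangle unit cube, outward-oriented."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box.apply_translation([0.5, 0.5, 0.5])
    s = TriSurface(np.asarray(box.vertices), np.asarray(box.faces))
    assert s.is_closed()
    return s


@pytest.fixture(scope="session")
def small_sphere():
    """Icosphere radius 8 mm at moderate resolution (162 vertices)."""
    m = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


@pytest.fixture(scope="session")
def fine_sphere():
    """Icosphere radius 2 mm, 4 subdivisions (2562 vertices)."""
    m = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


@pytest.fixture(scope="session")
def sphere_kernel(small_sphere):
    return lddmm.KernelParams.for_surface(small_sphere)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
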