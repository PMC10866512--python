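import numpy as np
import pytest

import meshcurv as mc


@pytest.fixture(scope="session")
def sphere10():
    """Fine unit-test sphere, r = 10 mm."""
    return mc.ideal.sphere(10.0, edge=1.0)


@pytest.fixture(scope="session")
def cylinder10():
    """Open cylinder r = 10 mm, L = 160 mm, no caps."""
    return mc.ideal.cylinder(10.0, 160.0, edge=1.2)


@pytest.fixture(scope="session")
def torus30_10():
    return mc.ideal.torus(30.0, 10.0, edge=1.5)


@pytest.fixture(scope="session")
def sphere10_curv(sphere10):
    return mc.per_vertex_shape_operator(sphere10.mesh)


@pytest.fixture(scope="session")
def cylinder10_curv(cylinder10):
    curv = mc.per_vertex_shape_operator(cylinder10.mesh)
    curv, area = mc.remove_rim_artifacts(cylinder10.mesh, curv)
    return curv, area


@pytest.fixture(scope="session")
def torus_curv(torus30_10):
    return mc.per_vertex_shape_operator(torus30_10.mesh)


@pytest.fixture(scope="session")
def rough_tube():
    """Bent tube with moderate surface roughness."""
    spec = mc.TubeSpec(radius=10.0, bump_amplitude=0.2, seed=3, edge=10 / 8)
    return mc.generate_tube(spec)


def make_single_triangle(area3: float = 3.0) -> mc.TriangleMesh:
    """Equilateral triangle of total area ``area3``."""
    side = np.sqrt(4.0 * area3 / np.sqrt(3.0))
    verts = np.array(
        [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]], float
    )
    return mc.TriangleMesh(verts, np.array([[0, 1, 2]]))
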