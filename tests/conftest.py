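import numpy as np
import pytest

from fluctfem.continuum import ContinuumModel
from fluctfem.materials import DEFAULT_TEST_MATERIAL, DragModel
from fluctfem.meshkit import TetMesh, make_cube_mesh, make_sphere_mesh


@pytest.fixture
def unit_tet_mesh():
    """Unit right tetrahedron (nm coordinates)."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    return TetMesh(nodes, np.array([[0, 1, 2, 3]]))


@pytest.fixture
def cube_mesh():
    return make_cube_mesh(2.0, 1)


@pytest.fixture
def cube_model(cube_mesh):
    drag = DragModel(solvent_viscosity=1e-3, node_radius=0.5e-9,
                     temperature=300.0)
    return ContinuumModel(cube_mesh, DEFAULT_TEST_MATERIAL, drag)


@pytest.fixture(scope="session")
def sphere_mesh():
    return make_sphere_mesh(5.0, 2.5)


@pytest.fixture(scope="session")
def sphere_model_session(sphere_mesh):
    drag = DragModel(solvent_viscosity=1e-3,
                     node_radius=5e-9 / sphere_mesh.n_nodes,
                     temperature=300.0)
    return ContinuumModel(sphere_mesh, DEFAULT_TEST_MATERIAL, drag)
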