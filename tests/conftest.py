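import numpy as np
import pytest

from stiflemorph.mesh_io import TriangleMesh
from stiflemorph.synthetic import LigamentSpec, constant_profile, make_ligament


@pytest.fixture
def tetra_mesh() -> TriangleMesh:
    """Unit tetrahedron, the smallest closed mesh."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces, label="ACL")


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    """Unit cube: 8 vertices, 12 triangles."""
    verts = np.array(
        [
            [x, y, z]
            for x in (0.0, 1.0)
            for y in (0.0, 1.0)
            for z in (0.0, 1.0)
        ]
    )
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],
            [4, 6, 7], [4, 7, 5],
            [0, 4, 5], [0, 5, 1],
            [2, 3, 7], [2, 7, 6],
            [0, 2, 6], [0, 6, 4],
            [1, 5, 7], [1, 7, 3],
        ]
    )
    return TriangleMesh(verts, faces, label="PLATEAU")


@pytest.fixture
def rat_tube() -> TriangleMesh:
    """Constant-area rat-scale ligament tube (0.26 mm^2, 3 mm)."""
    spec = LigamentSpec(
        length=3.0,
        area_profile=constant_profile(0.26),
        vertex_spacing=0.02,
        seed=11,
    )
    return make_ligament(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
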