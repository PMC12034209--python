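import numpy as np
import pytest
import trimesh

from morphoatlas.mesh import TriangleMesh


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


def icosphere(subdivisions=2, radius=1.0, specimen_id=""):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces), specimen_id)


@pytest.fixture(scope="session")
def icosahedron():
    return icosphere(subdivisions=0, radius=1.0)


@pytest.fixture(scope="session")
def sphere50():
    return icosphere(subdivisions=3, radius=50.0)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
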