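import numpy as np
import pytest

from gelshell import HydrogelMaterial, OgdenMaterial, TriMesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hydrogel():
    # mu = 1, chi/mu = 2.17: the bundled scenario parameters
    return HydrogelMaterial(mu=1.0, chi=2.17, k_res=1e-4)


@pytest.fixture
def ogden():
    return OgdenMaterial(mu_og=0.1, k_og=1.0, alpha=-20.0)


@pytest.fixture
def single_triangle():
    return TriMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        triangles=np.array([[0, 1, 2]]),
    )


@pytest.fixture
def unit_square():
    """Unit square split along the diagonal (0,0)-(1,1)."""
    return TriMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]),
        triangles=np.array([[0, 1, 2], [0, 2, 3]]),
    )


def random_rotation(rng):
    """Haar-ish random rotation via QR with positive diagonal."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_F(rng, spread=0.3):
    """Random deformation gradient with comfortably positive determinant."""
    while True:
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.2:
            return F
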