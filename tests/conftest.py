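import numpy as np
import pytest

from skullnav.geometry import LandmarkSet, RigidTransform, TriangleMesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tetrahedron():
    """Unit tetrahedron with outward-oriented faces (closed)."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]], dtype=np.int64)
    return TriangleMesh(v, f)


def make_cube():
    """Closed axis-aligned unit cube, 12 triangles."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0)
            [4, 5, 6], [4, 6, 7],  # top (z=1)
            [0, 1, 5], [0, 5, 4],  # front (y=0)
            [2, 3, 7], [2, 7, 6],  # back (y=1)
            [1, 2, 6], [1, 6, 5],  # right (x=1)
            [3, 0, 4], [3, 4, 7],  # left (x=0)
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, f)


@pytest.fixture
def cube():
    return make_cube()


@pytest.fixture
def icosahedron():
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, f)


def random_rigid(rng, max_translation=50.0):
    """Uniformly random proper rotation plus bounded translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(Q, t)


def random_landmarks(rng, n=6, scale=40.0, frame="image", prefix="L"):
    return LandmarkSet(
        [f"{prefix}{i+1}" for i in range(n)],
        rng.uniform(-scale, scale, size=(n, 3)),
        frame=frame,
    )


@pytest.fixture
def random_rigid_factory(rng):
    return lambda: random_rigid(rng)
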