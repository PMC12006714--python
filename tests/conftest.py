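import numpy as np
import pytest

from femquad.synthetic import FemurSpec, make_proximal_femur


@pytest.fixture(scope="session")
def default_femur():
    """One noiseless canonical femur shared across tests (read-only)."""
    return make_proximal_femur(FemurSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng):
    """A random rotation matrix and translation vector."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-100.0, 100.0, size=3)
    return Q, t
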