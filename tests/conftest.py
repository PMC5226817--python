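import numpy as np
import pytest

from chromisd import PolymerSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quartic_spec():
    return PolymerSpec(n_beads=20, ev_kind="quartic_repulsion")


@pytest.fixture
def lj_spec():
    return PolymerSpec(n_beads=20, ev_kind="lennard_jones")


def finite_difference_gradient(f, X, eps=1e-6):
    """Central finite differences of a scalar function of an (N, 3) array."""
    X = np.asarray(X, dtype=float)
    g = np.zeros_like(X)
    for i in range(X.shape[0]):
        for k in range(3):
            Xp = X.copy()
            Xp[i, k] += eps
            Xm = X.copy()
            Xm[i, k] -= eps
            g[i, k] = (f(Xp) - f(Xm)) / (2 * eps)
    return g


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(size=3) * 5.0
    return Q, t
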