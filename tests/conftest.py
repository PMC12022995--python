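import numpy as np
import pytest

from confsolv.synthetic_fixtures import make_toy_molecule


@pytest.fixture(scope="session")
def chain4():
    return make_toy_molecule("chain_n", n=4)


@pytest.fixture(scope="session")
def chain5():
    return make_toy_molecule("chain_n", n=5)


@pytest.fixture(scope="session")
def hbond_probe():
    return make_toy_molecule("hbond_probe")


@pytest.fixture(scope="session")
def ring6():
    return make_toy_molecule("ring6")


@pytest.fixture(scope="session")
def diatomic():
    return make_toy_molecule("diatomic", k=1000.0, r0=0.15)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def finite_difference_forces(energy_fn, coords, step=1e-5):
    """Central-difference forces -dE/dx, the independent oracle used
    throughout the force-consistency tests."""
    coords = np.asarray(coords, dtype=float)
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            cp = coords.copy(); cp[i, k] += step
            cm = coords.copy(); cm[i, k] -= step
            out[i, k] = -(energy_fn(cp) - energy_fn(cm)) / (2.0 * step)
    return out
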