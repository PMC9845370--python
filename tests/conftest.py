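import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from excitedvmc.systems import (
    HarmonicPotential,
    ModelSystem,
    MolecularSystem,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hydrogen():
    return MolecularSystem([1], [[0.0, 0.0, 0.0]], 1, 0)


@pytest.fixture
def harmonic():
    return ModelSystem(1, 1, HarmonicPotential(1.0), name="harmonic")


@pytest.fixture
def lithium_like():
    """A 3-electron, 2-nucleus toy for determinant/backflow machinery."""
    return MolecularSystem([3, 1], [[0, 0, 0], [0, 0, 3.0]], 2, 1)


def fd_grad_log(psi, x, eps=1e-5):
    """Central-difference gradient of ln|psi| (test oracle)."""
    B, N, D = x.shape
    out = np.zeros_like(x)
    for i in range(N):
        for a in range(D):
            p = x.copy()
            p[:, i, a] += eps
            m = x.copy()
            m[:, i, a] -= eps
            out[:, i, a] = (psi.sign_log(p)[1] - psi.sign_log(m)[1]) / (2 * eps)
    return out


def fd_lap_log(psi, x, eps=1e-4):
    """Central-difference total Laplacian of ln|psi| (test oracle)."""
    B, N, D = x.shape
    l0 = psi.sign_log(x)[1]
    out = np.zeros(B)
    for i in range(N):
        for a in range(D):
            p = x.copy()
            p[:, i, a] += eps
            m = x.copy()
            m[:, i, a] -= eps
            out += (psi.sign_log(p)[1] - 2 * l0 + psi.sign_log(m)[1]) / eps**2
    return out


def fd_param_grad_log(psi, x, eps=1e-6):
    th0 = psi.get_params().copy()
    out = np.zeros((x.shape[0], th0.size))
    for k in range(th0.size):
        t = th0.copy()
        t[k] += eps
        psi.set_params(t)
        lp = psi.sign_log(x)[1]
        t = th0.copy()
        t[k] -= eps
        psi.set_params(t)
        lm = psi.sign_log(x)[1]
        out[:, k] = (lp - lm) / (2 * eps)
    psi.set_params(th0)
    return out
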