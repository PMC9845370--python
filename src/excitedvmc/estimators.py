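"""Monte Carlo estimators for energies, overlaps, and mixed observables.

Overlaps of *unnormalized* states are estimated norm-free as the geometric
mean of the two directional ratio expectations

    S_ij = sgn(E_i[psi_j/psi_i]) * sqrt(E_i[psi_j/psi_i] * E_j[psi_i/psi_j]),

with batches drawn from |psi_i|^2 and |psi_j|^2 respectively; the same
construction with a local operator ratio (O psi_j)(r)/psi_j(r) inserted
gives general mixed matrix elements (transition dipoles in particular),
and reduces bit-exactly to the overlap for the identity operator.

Parameter gradients use the score-function (reweighting) convention: the
per-sample local values are held fixed and only the sampling weights are
differentiated, giving the covariance forms

    dE     = 2 E[(E_loc - E[E_loc]) dln|psi|],
    dO_ij  = (1/O_ij) { E_i[(R_ij - E_i[R_ij]) dln|psi_i|] E_j[R_ji]
                        + (i <-> j) }.

The omitted integrand-derivative terms vanish in expectation (Hermiticity
for the energy, norm cancellation for the overlap), so these estimators
are unbiased; being reweighting-exact, they also match finite differences
of the frozen-batch reweighted estimators to machine precision.

Heavy tails of the ratio psi_j/psi_i near nodes of psi_i are tamed by
capping |ratio| at a high per-batch quantile (capping rate reported);
local energies on the gradient path are winsorized at median +/- 5 MAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .systems import local_energy

__all__ = [
    "ScalarEstimate",
    "OverlapEstimate",
    "TransitionMoment",
    "LocalOperator",
    "Multiplicative",
    "HamiltonianOperator",
    "DipoleComponent",
    "energy_estimate",
    "overlap_estimate",
    "mixed_observable",
    "transition_dipole",
    "oscillator_strength",
    "grad_energy",
    "grad_overlap",
]

RATIO_CAP_QUANTILE = 0.999
WINSOR_MADS = 5.0
OVERLAP_FLOOR = 1e-8


@dataclass
class ScalarEstimate:
    value: float
    se: float
    n_eff: int
    variance: float = 0.0
    n_excluded: int = 0
    batch_id: Optional[int] = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass
class OverlapEstimate:
    value: float          # S_ij after sign resolution; 0 if signs disagree
    se: float
    mean_i: float         # E_i[psi_j/psi_i]
    mean_j: float         # E_j[psi_i/psi_j]
    signs_agree: bool
    cap_rate: float = 0.0


@dataclass
class TransitionMoment:
    d: np.ndarray                   # TDM vector, e*bohr (length = dimensionality)
    d_se: np.ndarray
    delta_e: float                  # excitation energy, Ha
    q: float = -1.0                 # charge convention per electron

    @property
    def d2(self) -> float:
        """Dipole strength |d|^2 (e^2 bohr^2)."""
        return float(np.sum(self.d**2))

    @property
    def oscillator_strength(self) -> float:
        return oscillator_strength(self.delta_e, self.d2)


# ---------------------------------------------------------------------------
# local operators


class LocalOperator:
    """Operator with a pointwise-computable local action (O psi)(r)/psi(r)."""

    def local_ratio(self, psi, x) -> np.ndarray:
        raise NotImplementedError


class Multiplicative(LocalOperator):
    """O = f(r): local ratio is just f(r)."""

    def __init__(self, f: Callable[[np.ndarray], np.ndarray]):
        self.f = f

    def local_ratio(self, psi, x):
        return self.f(x)


class Identity(Multiplicative):
    def __init__(self):
        super().__init__(lambda x: np.ones(x.shape[0]))


class DipoleComponent(Multiplicative):
    """mu_a = sum_k q x_{k,a} with q = -1 per electron."""

    def __init__(self, axis: int, q: float = -1.0):
        self.axis = axis
        self.q = q
        super().__init__(lambda x: q * np.sum(x[:, :, axis], axis=1))


class HamiltonianOperator(LocalOperator):
    """O = H: local ratio is the local energy of psi."""

    def __init__(self, system):
        self.system = system

    def local_ratio(self, psi, x):
        return local_energy(psi, self.system, x, check=False)


# ---------------------------------------------------------------------------
# helpers


def _winsorize(e: np.ndarray) -> np.ndarray:
    med = np.median(e)
    mad = np.mean(np.abs(e - med))
    if mad == 0.0:
        return e
    return np.clip(e, med - WINSOR_MADS * mad, med + WINSOR_MADS * mad)


def _cap_ratio(r: np.ndarray, quantile: float = RATIO_CAP_QUANTILE):
    """Cap |r| at its per-batch quantile; return capped values + rate."""
    a = np.abs(r)
    cap = np.quantile(a, quantile)
    capped = np.clip(r, -cap, cap)
    rate = float(np.mean(a > cap))
    return capped, rate


def _log_ratio(psi_num, psi_den, x) -> np.ndarray:
    """psi_num(x)/psi_den(x) in sign/log form (stable)."""
    sn, ln = psi_num.sign_log(x)
    sd, ld = psi_den.sign_log(x)
    with np.errstate(over="ignore", invalid="ignore"):
        out = sn * sd * np.exp(ln - ld)
    return np.where(np.isfinite(out), out, 0.0)


def _block_jackknife(fn, arrays, n_blocks: int = 20) -> float:
    """Jackknife SE of fn(arrays) over paired blocks of each array."""
    n = min(a.shape[0] for a in arrays)
    n_blocks = min(n_blocks, n)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    full = fn(*arrays)
    reps = []
    for b in range(n_blocks):
        sel = np.ones(n, dtype=bool)
        sel[edges[b]: edges[b + 1]] = False
        reps.append(fn(*[a[sel[: a.shape[0]]] for a in arrays]))
    reps = np.asarray(reps)
    return float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((reps - np.mean(reps)) ** 2)))


# ---------------------------------------------------------------------------
# estimators


def energy_estimate(psi, system, x, batch_id=None) -> ScalarEstimate:
    """Mean, SE and batch variance of the local energy over a |psi|^2 batch.

    Non-finite local energies are excluded and counted; more than 1%
    excluded raises a warning.  The reported value is the plain mean (no
    winsorization; that is applied on the gradient path only).
    """
    e = local_energy(psi, system, x, check=False)
    finite = np.isfinite(e)
    n_excl = int(np.sum(~finite))
    e = e[finite]
    if e.size == 0:
        raise FloatingPointError("no finite local energies in batch")
    if n_excl > 0.01 * finite.size:
        import warnings

        warnings.warn(f"{n_excl}/{finite.size} local energies non-finite")
    var = float(np.var(e))
    return ScalarEstimate(
        value=float(np.mean(e)),
        se=float(np.sqrt(var / e.size)),
        n_eff=int(e.size),
        variance=var,
        n_excluded=n_excl,
        batch_id=batch_id,
    )


def _geometric_mean_estimate(t_i, t_j):
    """Sign-resolved geometric mean of two directional means."""
    m_i, m_j = float(np.mean(t_i)), float(np.mean(t_j))
    prod = m_i * m_j
    agree = (np.sign(m_i) == np.sign(m_j)) and prod > 0
    if not agree:
        return 0.0, m_i, m_j, False
    return float(np.sign(m_i) * math.sqrt(prod)), m_i, m_j, True


def mixed_observable(op: LocalOperator, psi_i, psi_j, x_i, x_j,
                     cap=RATIO_CAP_QUANTILE) -> OverlapEstimate:
    """Norm-free mixed matrix element O_ij between unnormalized states.

    O_ij = sgn(E_i[O psi_j/psi_i]) sqrt(E_i[O psi_j/psi_i] E_j[O psi_i/psi_j]).

    If the two directional estimates disagree in sign the states are
    reported orthogonal (value 0, flag False).
    """
    t_i = op.local_ratio(psi_j, x_i) * _log_ratio(psi_j, psi_i, x_i)
    t_j = op.local_ratio(psi_i, x_j) * _log_ratio(psi_i, psi_j, x_j)
    t_i, rate_i = _cap_ratio(t_i, cap)
    t_j, rate_j = _cap_ratio(t_j, cap)
    value, m_i, m_j, agree = _geometric_mean_estimate(t_i, t_j)

    def stat(a, b):
        return _geometric_mean_estimate(a, b)[0]

    se = _block_jackknife(stat, (t_i, t_j))
    return OverlapEstimate(
        value=value, se=se, mean_i=m_i, mean_j=m_j,
        signs_agree=agree, cap_rate=0.5 * (rate_i + rate_j),
    )


def overlap_estimate(psi_i, psi_j, x_i, x_j, cap=RATIO_CAP_QUANTILE) -> OverlapEstimate:
    """Pairwise overlap S_ij of unnormalized states (geometric-mean form).

    S_ii is exactly 1 (same object passed twice).
    """
    if psi_i is psi_j:
        return OverlapEstimate(1.0, 0.0, 1.0, 1.0, True, 0.0)
    return mixed_observable(Identity(), psi_i, psi_j, x_i, x_j, cap=cap)


def transition_dipole(psi_i, psi_j, x_i, x_j, delta_e: float,
                      q: float = -1.0) -> TransitionMoment:
    """TDM d_ij = <i| sum_k q r_k |j> via the norm-free mixed estimator.

    The overall sign of d is a phase convention and not an observable;
    only |d| and the dipole strength d^2 are physical.
    """
    dim = x_i.shape[2]
    vals, ses = np.zeros(dim), np.zeros(dim)
    for a in range(dim):
        est = mixed_observable(DipoleComponent(a, q), psi_i, psi_j, x_i, x_j)
        vals[a], ses[a] = est.value, est.se
    return TransitionMoment(d=vals, d_se=ses, delta_e=float(delta_e), q=q)


def oscillator_strength(delta_e: float, d2: float) -> float:
    """f = (2/3) dE d^2 (atomic units, dimensionless).

    Computed regardless of the sign of dE; a negative dE signals a state
    ordering problem upstream and simply yields a negative f.
    """
    return (2.0 / 3.0) * delta_e * d2


# ---------------------------------------------------------------------------
# gradients


def _masked(psi, grad):
    out = np.where(psi.trainable_mask(), grad, 0.0)
    return out


def _grad_energy_core(psi, system, x, winsorize):
    e = local_energy(psi, system, x, check=False)
    glp = psi.param_grad_log(x)
    finite = np.isfinite(e) & np.all(np.isfinite(glp), axis=1)
    e, glp = e[finite], glp[finite]
    if winsorize:
        e = _winsorize(e)
    m = np.mean(e)
    grad = 2.0 * ((e - m) @ (glp - np.mean(glp, axis=0))) / e.size
    return _masked(psi, grad), float(m)


def grad_energy(psi, system, x, winsorize: bool = True) -> np.ndarray:
    """Energy gradient 2 E[(E_loc - mean) dln|psi|] (score-function form).

    Frozen parameter groups receive exact zeros; non-finite samples are
    excluded; local energies are winsorized (gradient path only).
    """
    return _grad_energy_core(psi, system, x, winsorize)[0]


def _mixed_gradient_pair(t_i, t_j, glp_i, glp_j, value):
    """Covariance-form gradients of the geometric-mean estimator."""
    m_i, m_j = np.mean(t_i), np.mean(t_j)
    cov_i = ((t_i - m_i) @ (glp_i - np.mean(glp_i, axis=0))) / t_i.size
    cov_j = ((t_j - m_j) @ (glp_j - np.mean(glp_j, axis=0))) / t_j.size
    g_i = cov_i * m_j / value
    g_j = cov_j * m_i / value
    return g_i, g_j


def grad_overlap(psi_i, psi_j, x_i, x_j, detach_lower: bool = True,
                 clip_norm: Optional[float] = None, cap=RATIO_CAP_QUANTILE):
    """Gradient of S_ij with respect to the parameters of state i (and j).

    With ``detach_lower`` the lower state j is treated as a constant and
    only the state-i gradient is returned (second element None).  Overlaps
    whose magnitude falls below a floor, or whose directional estimates
    disagree in sign, yield exact-zero gradients (the estimator reported
    orthogonality).  ``clip_norm`` applies a global gradient-norm clip.
    """
    t_i, _ = _cap_ratio(_log_ratio(psi_j, psi_i, x_i), cap)
    t_j, _ = _cap_ratio(_log_ratio(psi_i, psi_j, x_j), cap)
    value, m_i, m_j, agree = _geometric_mean_estimate(t_i, t_j)
    if (not agree) or abs(value) < OVERLAP_FLOOR:
        zi = np.zeros(psi_i.n_params)
        zj = None if detach_lower else np.zeros(psi_j.n_params)
        return zi, zj
    glp_i = psi_i.param_grad_log(x_i)
    glp_j = psi_j.param_grad_log(x_j)
    g_i, g_j = _mixed_gradient_pair(t_i, t_j, glp_i, glp_j, value)
    g_i = _masked(psi_i, g_i)
    g_j = None if detach_lower else _masked(psi_j, g_j)
    if clip_norm is not None:
        g_i = clip_gradient(g_i, clip_norm)
        if g_j is not None:
            g_j = clip_gradient(g_j, clip_norm)
    return g_i, g_j


def grad_mixed_observable(op: LocalOperator, psi_i, psi_j, x_i, x_j,
                          cap=RATIO_CAP_QUANTILE):
    """Score-function gradient of the general mixed estimator O_ij.

    For i is j with the Hamiltonian this reduces (up to the sign of the
    energy, since O_ii = |E|) to :func:`grad_energy` on the same batch:
    both paths share the covariance kernel and the winsorization policy.
    """
    if psi_i is psi_j and isinstance(op, HamiltonianOperator):
        grad, m = _grad_energy_core(psi_i, op.system, x_i, winsorize=True)
        return np.sign(m) * grad, None
    t_i, _ = _cap_ratio(op.local_ratio(psi_j, x_i) * _log_ratio(psi_j, psi_i, x_i), cap)
    t_j, _ = _cap_ratio(op.local_ratio(psi_i, x_j) * _log_ratio(psi_i, psi_j, x_j), cap)
    value, m_i, m_j, agree = _geometric_mean_estimate(t_i, t_j)
    if (not agree) or abs(value) < OVERLAP_FLOOR:
        return np.zeros(psi_i.n_params), np.zeros(psi_j.n_params)
    glp_i = psi_i.param_grad_log(x_i)
    glp_j = psi_j.param_grad_log(x_j)
    g_i, g_j = _mixed_gradient_pair(t_i, t_j, glp_i, glp_j, value)
    return _masked(psi_i, g_i), _masked(psi_j, g_j)


def clip_gradient(g: np.ndarray, max_norm: float) -> np.ndarray:
    norm = float(np.linalg.norm(g))
    if norm > max_norm > 0:
        return g * (max_norm / norm)
    return g
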