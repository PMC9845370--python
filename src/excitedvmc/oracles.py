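"""Brute-force ground truth for low-dimensional systems.

A second-order finite-difference eigensolver on uniform grids provides
reference spectra and wavefunctions for the solvable systems (1D/2D one
particle, 1D two particles with optional exchange symmetry), dense-grid
quadrature provides exact matrix elements, and the two-state mixture
fixture provides analytically known overlaps and energies for calibrating
every Monte Carlo estimator:

    psi_eps = sqrt(1-eps) psi_1 + sqrt(eps) psi_0,
    <psi_0|psi_eps> = sqrt(eps),
    <psi_eps|H|psi_eps> = (1-eps) E_1 + eps E_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eigh_tridiagonal

from .states import LinearCombination
from .systems import ModelSystem

__all__ = ["GridSpec", "GridSolution", "MixtureFixture", "grid_eigensolve",
           "make_mixture", "quadrature_observable"]

BOUNDARY_MASS_TOL = 1e-6


@dataclass(frozen=True)
class GridSpec:
    extent: float = 8.0     # grid covers [-extent, extent] (or [0, L] for a box)
    n_points: int = 801
    lower: Optional[float] = None

    def axis(self):
        lo = -self.extent if self.lower is None else self.lower
        return np.linspace(lo, self.extent, self.n_points)


@dataclass
class GridSolution:
    """Lowest eigenpairs of a discretized Hamiltonian.

    Eigenfunctions are orthonormal under the grid quadrature
    sum(f g) * h^d; ``interpolate`` evaluates them off-grid.
    """

    xs: np.ndarray               # axis points (shared per dimension)
    h: float
    ndim: int                    # total discretized dimension (d * particles)
    energies: np.ndarray         # (n_states,)
    functions: np.ndarray        # (n_states, n_points**ndim) flattened
    swap_parity: Optional[np.ndarray] = None

    @property
    def weights(self) -> float:
        return self.h**self.ndim

    def function_nd(self, k):
        n = self.xs.size
        return self.functions[k].reshape((n,) * self.ndim)

    def interpolate(self, k):
        from scipy.interpolate import RegularGridInterpolator

        grid = (self.xs,) * self.ndim
        return RegularGridInterpolator(grid, self.function_nd(k),
                                       bounds_error=False, fill_value=0.0)


def _laplacian_1d(n, h):
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1]) / h**2


def grid_eigensolve(system: ModelSystem, n_states: int,
                    grid: GridSpec = GridSpec(),
                    exchange: str = "none") -> GridSolution:
    """Finite-difference diagonalization of a model Hamiltonian.

    Supports one particle in 1-2 dimensions and two particles in 1D
    (tensor-product grid).  For two-particle systems ``exchange`` selects
    the symmetry sector: "none", "symmetric" (bosonic) or "antisymmetric"
    (fermionic, like-spin).  Refuses if any requested eigenfunction
    carries more than BOUNDARY_MASS_TOL probability on the boundary shell,
    which indicates insufficient extent.
    """
    if exchange not in ("none", "symmetric", "antisymmetric"):
        raise ValueError("exchange must be none/symmetric/antisymmetric")
    xs = grid.axis()
    n = xs.size
    h = xs[1] - xs[0]
    ndim = system.d * system.n_particles
    if n**ndim > 2_000_000:
        raise ValueError("discretized dimension too large for the oracle")

    if ndim == 1:
        pts = xs.reshape(-1, 1, 1)
        v = _potential_on(system, pts)
        # infinite-potential points are removed from the operator, which
        # imposes the Dirichlet condition exactly (hard walls)
        alive = np.isfinite(v)
        diag = 1.0 / h**2 + v[alive]
        keep_idx = np.where(alive)[0]
        off = np.where(np.diff(keep_idx) == 1, -0.5 / h**2, 0.0)
        evals, evecs = eigh_tridiagonal(diag, off, select="i",
                                        select_range=(0, n_states - 1))
        funcs = np.zeros((n_states, n))
        funcs[:, alive] = evecs.T
        parity = None
    else:
        lap1 = _laplacian_1d(n, h)
        eye = sp.identity(n)
        if ndim == 2:
            lap = sp.kron(lap1, eye) + sp.kron(eye, lap1)
        else:
            raise ValueError("oracle supports at most 2 discretized dimensions")
        pts = _tensor_points(xs, system)
        v = _potential_on(system, pts)
        alive = np.isfinite(v)
        ham = (-0.5 * lap + sp.diags(np.where(alive, v, 0.0))).tocsr()
        if not alive.all():
            ham = ham[alive][:, alive]
        k = min(max(3 * n_states + 6, n_states), int(alive.sum()) - 2)
        evals, evecs = spla.eigsh(ham.tocsc(), k=k, which="SA")
        if not alive.all():
            full = np.zeros((n * n, evecs.shape[1]))
            full[alive] = evecs
            evecs = full
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        funcs = evecs.T
        parity = None
        if system.n_particles == 2:
            # project onto the requested exchange sector; degenerate levels
            # come out of the sparse solver as arbitrary parity mixtures,
            # so filtering by raw parity is not enough
            def swap(f):
                return f.reshape(n, n).T.ravel()

            if exchange == "none":
                parity = np.array([
                    float(f @ swap(f) / (f @ f)) for f in funcs
                ])
            else:
                sgn = 1.0 if exchange == "symmetric" else -1.0
                kept_f, kept_e = [], []
                for e, f in zip(evals, funcs):
                    proj = 0.5 * (f + sgn * swap(f))
                    nrm = np.linalg.norm(proj)
                    if nrm < 1e-4:
                        continue
                    proj = proj / nrm
                    # orthogonalize against already-kept functions so a
                    # degenerate subspace is not double-counted
                    for g in kept_f:
                        proj = proj - (g @ proj) * g
                    nrm = np.linalg.norm(proj)
                    if nrm < 1e-6:
                        continue
                    kept_f.append(proj / nrm)
                    kept_e.append(e)
                funcs = np.array(kept_f)
                evals = np.array(kept_e)
                parity = np.full(len(kept_e), sgn)
        funcs, evals = funcs[:n_states], evals[:n_states]
        parity = None if parity is None else parity[:n_states]

    # normalize under grid quadrature and fix a sign convention
    w = h ** (ndim if ndim > 1 else 1)
    funcs = funcs / np.sqrt(np.sum(funcs**2, axis=1, keepdims=True) * w)
    for f in funcs:
        idx = np.argmax(np.abs(f))
        if f[idx] < 0:
            f *= -1.0
    # boundary-mass check
    for k, f in enumerate(funcs):
        fn = f.reshape((n,) * (ndim if ndim > 1 else 1))
        edge = np.zeros_like(fn, dtype=bool)
        for ax in range(fn.ndim):
            sl = [slice(None)] * fn.ndim
            sl[ax] = [0, -1]
            edge[tuple(sl)] = True
        mass = float(np.sum(fn[edge] ** 2) * w)
        if mass > BOUNDARY_MASS_TOL:
            raise ValueError(
                f"eigenfunction {k} has boundary mass {mass:.2e}; "
                "increase the grid extent"
            )
    return GridSolution(xs=xs, h=h, ndim=ndim, energies=np.asarray(evals[:n_states]),
                        functions=funcs, swap_parity=parity)


def _potential_on(system, pts):
    from .systems import potential_energy

    # infinities (hard walls) are kept: the solver removes those points
    return potential_energy(system, pts)


def _tensor_points(xs, system):
    n = xs.size
    if system.n_particles == 2 and system.d == 1:
        a, b = np.meshgrid(xs, xs, indexing="ij")
        return np.stack([a.ravel(), b.ravel()], axis=1)[:, :, None]
    if system.n_particles == 1 and system.d == 2:
        a, b = np.meshgrid(xs, xs, indexing="ij")
        return np.stack([a.ravel(), b.ravel()], axis=1)[:, None, :]
    raise ValueError("unsupported tensor grid layout")


def quadrature_observable(op, state_a, state_b, grid: GridSpec = GridSpec(),
                          normalize: bool = True) -> float:
    """Exact (Riemann-sum) matrix element <a| op |b> on a dense 1D grid.

    ``state_a``/``state_b`` are wavefunctions (callables via sign/log) of
    one particle in 1D; ``op`` is a multiplicative callable op(x) -> array
    (or None for the identity).  With ``normalize`` the states are
    normalized under the same quadrature, matching the Monte Carlo
    estimators' normalized-state semantics.
    """
    xs = grid.axis()
    pts = xs.reshape(-1, 1, 1)
    fa = state_a(pts)
    fb = state_b(pts)
    w = xs[1] - xs[0]
    o = np.ones_like(xs) if op is None else op(pts)
    val = float(np.sum(fa * o * fb) * w)
    if normalize:
        na = float(np.sum(fa * fa) * w)
        nb = float(np.sum(fb * fb) * w)
        val /= np.sqrt(na * nb)
    return val


@dataclass
class MixtureFixture:
    """Two-state mixture with exactly known overlap and energy."""

    eps: float
    state0: object
    state1: object
    mixed: LinearCombination
    exact_overlap: float
    exact_energy: Optional[float]


def make_mixture(eps: float, state0, state1, grid: Optional[GridSpec] = None,
                 orthonormal_tol: float = 1e-6) -> MixtureFixture:
    """psi_eps = sqrt(1-eps) psi_1 + sqrt(eps) psi_0 as an evaluable state.

    The inputs must be orthonormal; this is verified by quadrature when a
    grid is supplied (states carrying closed-form normalization may skip
    the check by passing grid=None).
    """
    if not (0.0 <= eps <= 1.0):
        raise ValueError("eps must lie in [0, 1]")
    if grid is not None:
        s00 = quadrature_observable(None, state0, state0, grid, normalize=False)
        s11 = quadrature_observable(None, state1, state1, grid, normalize=False)
        s01 = quadrature_observable(None, state0, state1, grid, normalize=False)
        if abs(s00 - 1) > orthonormal_tol or abs(s11 - 1) > orthonormal_tol \
                or abs(s01) > orthonormal_tol:
            raise ValueError(
                f"input states not orthonormal: <0|0>={s00:.2e}, "
                f"<1|1>={s11:.2e}, <0|1>={s01:.2e}"
            )
    mixed = LinearCombination([state1, state0],
                              [np.sqrt(1.0 - eps), np.sqrt(eps)], trainable=False)
    e0 = getattr(state0, "energy", None)
    e1 = getattr(state1, "energy", None)
    exact_e = None if (e0 is None or e1 is None) else (1 - eps) * e1 + eps * e0
    return MixtureFixture(eps=eps, state0=state0, state1=state1, mixed=mixed,
                          exact_overlap=float(np.sqrt(eps)), exact_energy=exact_e)
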