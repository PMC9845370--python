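"""Hamiltonians and local energies.

Two kinds of systems are supported: full Born-Oppenheimer molecular Coulomb
Hamiltonians (clamped nuclei, atomic units throughout) and low-dimensional
analytic model potentials (harmonic trap, infinite box, soft Coulomb) that
serve as exactly solvable references.

Electron configurations are plain arrays of shape ``(N, d)`` or batched
``(B, N, d)``, with the first ``n_up`` particle slots carrying spin up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SingularConfigurationError",
    "NumericalBreakdownError",
    "MolecularSystem",
    "ModelSystem",
    "HarmonicPotential",
    "BoxPotential",
    "SoftCoulombPotential",
    "SoftCoulombInteraction",
    "potential_energy",
    "local_energy",
    "kinetic_energy",
]

ANGSTROM_TO_BOHR = 1.8897259886


class SingularConfigurationError(ValueError):
    """Raised when two particles (or a particle and a nucleus) coincide.

    Samplers catch this (or observe non-finite values) and reject the
    offending proposal; configurations are never silently clamped.
    """

    def __init__(self, message: str, conf: Optional[np.ndarray] = None):
        super().__init__(message)
        self.conf = conf


class NumericalBreakdownError(FloatingPointError):
    """Raised when a wavefunction derivative is non-finite at a configuration."""

    def __init__(self, message: str, conf: Optional[np.ndarray] = None):
        super().__init__(message)
        self.conf = conf


@dataclass(frozen=True)
class MolecularSystem:
    """Clamped-nuclei molecular Coulomb Hamiltonian.

    Parameters
    ----------
    charges : integer nuclear charges ``Z_I >= 1``.
    positions : nuclear coordinates in bohr, shape ``(M, 3)``.
    n_up, n_down : electron counts per spin channel (``n_up >= n_down >= 0``).
    """

    charges: np.ndarray
    positions: np.ndarray
    n_up: int
    n_down: int

    def __post_init__(self):
        charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if positions.shape != (charges.shape[0], 3):
            raise ValueError(
                f"positions must have shape ({charges.shape[0]}, 3), got {positions.shape}"
            )
        if not np.all(np.isfinite(positions)):
            raise ValueError("nuclear positions must be finite")
        if np.any(charges < 1) or np.any(charges != np.round(charges)):
            raise ValueError("nuclear charges must be positive integers")
        if not (self.n_up >= self.n_down >= 0):
            raise ValueError("require n_up >= n_down >= 0")
        if self.n_up + self.n_down < 1:
            raise ValueError("need at least one electron")
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "positions", positions)

    @property
    def n_electrons(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_nuclei(self) -> int:
        return len(self.charges)

    @property
    def d(self) -> int:
        return 3

    @property
    def spin_projection(self) -> float:
        """S_z eigenvalue M = (N_up - N_down)/2, fixed by construction."""
        return 0.5 * (self.n_up - self.n_down)

    @property
    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.n_nuclei):
            for j in range(i + 1, self.n_nuclei):
                e += self.charges[i] * self.charges[j] / np.linalg.norm(
                    self.positions[i] - self.positions[j]
                )
        return float(e)

    def spins(self) -> np.ndarray:
        """+1 for the first n_up slots, -1 for the rest."""
        return np.concatenate([np.ones(self.n_up), -np.ones(self.n_down)])


@dataclass(frozen=True)
class HarmonicPotential:
    """Isotropic harmonic trap V = 1/2 omega^2 |r|^2."""

    omega: float = 1.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # x: (..., N, d) -> (...,)
        return 0.5 * self.omega**2 * np.sum(x**2, axis=(-1, -2))


@dataclass(frozen=True)
class BoxPotential:
    """Infinite square well on (0, L)^d; infinite outside."""

    length: float = 1.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        inside = np.all((x > 0.0) & (x < self.length), axis=(-1, -2))
        return np.where(inside, 0.0, np.inf)


@dataclass(frozen=True)
class SoftCoulombPotential:
    """Attractive soft-Coulomb well -Z / sqrt(softening^2 + |r|^2) per particle."""

    z: float = 1.0
    softening: float = 1.0

    def __post_init__(self):
        if self.z <= 0 or self.softening <= 0:
            raise ValueError("z and softening must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        r2 = np.sum(x**2, axis=-1)  # (..., N)
        return np.sum(-self.z / np.sqrt(self.softening**2 + r2), axis=-1)


@dataclass(frozen=True)
class SoftCoulombInteraction:
    """Repulsive pair interaction 1 / sqrt(softening^2 + r_ij^2)."""

    softening: float = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[-2]
        out = np.zeros(x.shape[:-2])
        for i in range(n):
            for j in range(i + 1, n):
                r2 = np.sum((x[..., i, :] - x[..., j, :]) ** 2, axis=-1)
                out = out + 1.0 / np.sqrt(self.softening**2 + r2)
        return out


@dataclass(frozen=True)
class ModelSystem:
    """Analytic model system in d dimensions (oracle territory).

    The potential is any callable mapping ``(..., N, d)`` configurations to
    ``(...)`` energies; ``interaction`` optionally adds a pairwise term.
    """

    d: int
    n_particles: int
    potential: object
    interaction: Optional[object] = None
    n_up: Optional[int] = None
    n_down: Optional[int] = None
    name: str = ""

    def __post_init__(self):
        if not (1 <= self.d <= 3):
            raise ValueError("dimensionality must be 1-3")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")

    @property
    def n_electrons(self) -> int:
        return self.n_particles


def _as_batch(conf: np.ndarray, n: int, d: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(conf, dtype=float)
    if x.ndim == 1:
        x = x.reshape(n, d)
    if x.ndim == 2:
        return x[None], True
    return x, False


def potential_energy(system, conf: np.ndarray) -> np.ndarray:
    """Total potential energy V(r) in hartree.

    For molecular systems this is electron-electron repulsion minus
    electron-nucleus attraction plus the (constant) nuclear-nuclear
    repulsion, so downstream energies are total energies.

    Raises
    ------
    SingularConfigurationError
        if any electron coincides exactly with a nucleus or another electron.
    """
    if isinstance(system, ModelSystem):
        x, single = _as_batch(conf, system.n_particles, system.d)
        if x.shape[-2:] != (system.n_particles, system.d):
            raise ValueError(f"configuration shape {x.shape} does not match system")
        if not np.all(np.isfinite(x)):
            raise ValueError("configuration must be finite")
        v = system.potential(x)
        if system.interaction is not None:
            v = v + system.interaction(x)
        return float(v[0]) if single else v

    x, single = _as_batch(conf, system.n_electrons, 3)
    if x.shape[-2:] != (system.n_electrons, 3):
        raise ValueError(f"configuration shape {x.shape} does not match system")
    if not np.all(np.isfinite(x)):
        raise ValueError("configuration must be finite")
    n = system.n_electrons
    v = np.full(x.shape[0], system.nuclear_repulsion)
    # electron-nucleus attraction
    den = x[:, :, None, :] - system.positions[None, None, :, :]
    dist_en = np.linalg.norm(den, axis=-1)  # (B, N, M)
    if np.any(dist_en == 0.0):
        raise SingularConfigurationError("electron coincides with a nucleus", conf=conf)
    v = v - np.sum(system.charges[None, None, :] / dist_en, axis=(1, 2))
    # electron-electron repulsion
    for i in range(n):
        for j in range(i + 1, n):
            rij = np.linalg.norm(x[:, i] - x[:, j], axis=-1)
            if np.any(rij == 0.0):
                raise SingularConfigurationError(
                    "two electrons coincide", conf=conf
                )
            v = v + 1.0 / rij
    return float(v[0]) if single else v


def kinetic_energy(psi, conf: np.ndarray) -> np.ndarray:
    """-1/2 sum_i [lap_i ln|psi| + |grad_i ln|psi||^2], the log-domain identity."""
    lap = psi.lap_log(conf)
    grad = psi.grad_log(conf)
    return -0.5 * (lap + np.sum(grad**2, axis=(-1, -2)))


def local_energy(psi, system, conf: np.ndarray, check: bool = True) -> np.ndarray:
    """Local energy E_loc(r) = H psi(r) / psi(r), from exact derivatives.

    ``check=True`` raises :class:`NumericalBreakdownError` if a derivative is
    non-finite at a configuration where the potential itself is finite;
    batched callers typically pass ``check=False`` and mask instead.
    """
    n = system.n_electrons
    d = system.d if isinstance(system, ModelSystem) else 3
    x, single = _as_batch(conf, n, d)
    v = potential_energy(system, x)
    e = kinetic_energy(psi, x) + v
    if check:
        bad = ~np.isfinite(e) & np.isfinite(v)
        if np.any(bad):
            raise NumericalBreakdownError(
                "non-finite local energy from wavefunction derivatives",
                conf=x[bad][0],
            )
    return float(e[0]) if single else e
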