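"""Metropolis-adjusted Langevin sampling of |psi|^2.

Each trial state keeps its own walker ensemble and RNG stream across
training.  Proposals follow the drifted-Gaussian (Langevin) kernel

    r' = r + (delta^2 / 2) * grad ln|psi|^2 (r) + delta * xi,

accepted with the Metropolis-Hastings ratio for that kernel, which makes
|psi|^2 the exact stationary law.  Proposals landing on nodes (sign 0) or
producing non-finite values are rejected outright; walkers whose *current*
drift turns non-finite are reinitialized and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .systems import MolecularSystem, ModelSystem

__all__ = ["WalkerEnsemble", "init_walkers", "langevin_step", "run_steps",
           "tune_step_size", "sample_batches"]

TARGET_ACCEPTANCE = 0.57  # Langevin optimal-scaling target
DELTA_MIN, DELTA_MAX = 1e-4, 10.0
DRIFT_CAP = 1.0  # max drift displacement in units of delta*sqrt(N*d)


def _drift(psi, x, delta):
    """Drift displacement (delta^2/2) grad ln|psi|^2, norm-capped per walker.

    Near nodes the raw drift diverges and uncapped MALA walkers freeze
    (the reverse-proposal density underflows); capping the displacement at
    a multiple of the noise scale removes the pathology.  The cap is a
    deterministic function of the position, applied identically in the
    forward and reverse kernels, so detailed balance is preserved exactly.
    """
    v = delta**2 * psi.grad_log(x)
    norm = np.sqrt(np.sum(v**2, axis=(1, 2), keepdims=True))
    cap = DRIFT_CAP * delta * np.sqrt(x.shape[1] * x.shape[2])
    with np.errstate(invalid="ignore"):
        scale = np.where(norm > cap, cap / norm, 1.0)
    return v * scale


@dataclass
class WalkerEnsemble:
    """State of one |psi|^2 Markov chain (B parallel walkers)."""

    x: np.ndarray                 # (B, N, d)
    log_abs: np.ndarray           # cached ln|psi| at x
    rng: np.random.Generator
    delta: float = 0.3
    n_accepted: int = 0
    n_proposed: int = 0
    n_reinit: int = 0
    freeze_tuning: bool = False   # time-homogeneous chains during estimation

    @property
    def batch_size(self) -> int:
        return self.x.shape[0]

    @property
    def acceptance(self) -> float:
        if self.n_proposed == 0:
            return 0.0
        return self.n_accepted / self.n_proposed

    def reset_statistics(self):
        self.n_accepted = 0
        self.n_proposed = 0


def _initial_positions(system, B, n, d, rng):
    if isinstance(system, MolecularSystem):
        # electrons perturb nuclear sites, round-robin
        centers = system.positions[np.arange(n) % system.n_nuclei]
        return centers[None] + rng.normal(size=(B, n, d))
    return rng.normal(size=(B, n, d))


def init_walkers(psi, system, B: int, seed, burn_in: int = 200,
                 delta: float = 0.3) -> WalkerEnsemble:
    """Fresh ensemble of B walkers, burned in; deterministic given seed.

    ``seed`` may be an int or a numpy Generator (for spawned streams).
    """
    if B < 1:
        raise ValueError("batch size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = psi.n_particles
    d = psi.d
    for attempt in range(5):
        x = _initial_positions(system, B, n, d, rng)
        sign, log = psi.sign_log(x)
        alive = (sign != 0) & np.isfinite(log)
        if np.any(alive):
            break
    else:
        raise RuntimeError("all initial walkers landed on nodes; check the ansatz")
    if not np.all(alive):
        # recycle living walkers into dead slots
        idx = np.where(alive)[0]
        fill = idx[rng.integers(0, idx.size, size=B)]
        x = np.where(alive[:, None, None], x, x[fill])
        log = np.where(alive, log, log[fill])
    ens = WalkerEnsemble(x=x, log_abs=log, rng=rng, delta=delta)
    for k in range(burn_in):
        langevin_step(ens, psi)
        if (k + 1) % 50 == 0:
            tune_step_size(ens)
    ens.reset_statistics()
    return ens


def langevin_step(ens: WalkerEnsemble, psi) -> WalkerEnsemble:
    """One Metropolis-adjusted Langevin move for every walker (in place)."""
    x = ens.x
    delta = ens.delta
    B = x.shape[0]
    drift = _drift(psi, x, delta)
    bad = ~np.all(np.isfinite(drift), axis=(1, 2))
    if np.any(bad):
        # walkers stuck at breakdown points are reinitialized from peers
        ens.n_reinit += int(np.sum(bad))
        good = np.where(~bad)[0]
        if good.size == 0:
            raise RuntimeError("all walkers have non-finite drift")
        fill = good[ens.rng.integers(0, good.size, size=B)]
        x = np.where(bad[:, None, None], x[fill], x)
        ens.log_abs = np.where(bad, ens.log_abs[fill], ens.log_abs)
        drift = np.where(bad[:, None, None], drift[fill], drift)
        ens.x = x
    xi = ens.rng.normal(size=x.shape)
    y = x + drift + delta * xi
    sign_y, log_y = psi.sign_log(y)
    with np.errstate(invalid="ignore"):
        drift_y = _drift(psi, y, delta)
        fwd = -np.sum((y - x - drift) ** 2, axis=(1, 2)) / (2.0 * delta**2)
        rev = -np.sum((x - y - drift_y) ** 2, axis=(1, 2)) / (2.0 * delta**2)
        log_ratio = 2.0 * (log_y - ens.log_abs) + rev - fwd
    ok = (sign_y != 0) & np.isfinite(log_y) & np.isfinite(log_ratio)
    u = ens.rng.random(B)
    accept = ok & (np.log(u) < log_ratio)
    ens.x = np.where(accept[:, None, None], y, x)
    ens.log_abs = np.where(accept, log_y, ens.log_abs)
    ens.n_proposed += B
    ens.n_accepted += int(np.sum(accept))
    return ens


def tune_step_size(ens: WalkerEnsemble) -> WalkerEnsemble:
    """Multiplicative adaptation of delta toward the target acceptance.

    Frozen (no-op) while ``freeze_tuning`` is set so that chains are
    time-homogeneous during estimator evaluation windows.
    """
    if ens.freeze_tuning or ens.n_proposed < 50:
        return ens
    acc = float(np.clip(ens.acceptance, 0.3, 0.9))
    ens.delta = float(np.clip(
        ens.delta * np.exp(acc - TARGET_ACCEPTANCE), DELTA_MIN, DELTA_MAX
    ))
    ens.reset_statistics()
    return ens


def run_steps(ens: WalkerEnsemble, psi, n_steps: int, tune_every: int = 0):
    """Advance the chain n_steps; optionally retune delta periodically."""
    for k in range(n_steps):
        langevin_step(ens, psi)
        if tune_every and (k + 1) % tune_every == 0:
            tune_step_size(ens)
    return ens


def resync(ens: WalkerEnsemble, psi):
    """Refresh cached ln|psi| after a parameter update."""
    _, ens.log_abs = psi.sign_log(ens.x)
    return ens


def sample_batches(ens: WalkerEnsemble, psi, n_samples: int,
                   thin: int = 10) -> np.ndarray:
    """Collect ~n_samples decorrelated configurations with frozen tuning."""
    ens.freeze_tuning = True
    rounds = int(np.ceil(n_samples / ens.batch_size))
    out = []
    for _ in range(rounds):
        run_steps(ens, psi, thin)
        out.append(ens.x.copy())
    ens.freeze_tuning = False
    return np.concatenate(out, axis=0)[:n_samples]
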