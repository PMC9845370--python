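"""Joint excited-state optimization with an overlap penalty.

n trial states are optimized together by stochastic gradient descent on

    L = sum_i E_i[E_loc,i] + alpha * sum_{i>j} (1/(1 - |S_ij|) - 1),

where each expectation runs over that state's own |psi_i|^2 walker
ensemble.  The penalty diverges when two states collapse onto each other
and is linear near orthogonality, so any positive alpha stabilizes an
orthogonal solution.  Gradients are detached onto the lower-lying states:
the ground state performs unconstrained energy minimization and state i
feels only its overlaps with states j < i.

Energy means and variances are tracked per iteration, exponentially
smoothed (bias-corrected), and checkpointed at a fixed cadence; the
smoothed variance series drives the variance-matching rule used for
excitation energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import estimators as est
from .sampler import init_walkers, run_steps, resync, sample_batches, tune_step_size

__all__ = [
    "PenaltyConfig",
    "TrainingConfig",
    "TrainingTrace",
    "SpectrumResult",
    "TrainingDivergence",
    "penalty",
    "penalty_deriv",
    "joint_loss",
    "gradient_assembly",
    "train",
    "smooth_statistics",
    "variance_match",
    "evaluate_states",
]


@dataclass
class PenaltyConfig:
    """Overlap-penalty settings.

    alpha : weight of the penalty term (Ha per dimensionless penalty unit);
        constant by default, optionally ramped linearly.
    ramp : optional (alpha_start, alpha_end, n_iterations).
    s_max : clamp on |S| inside the penalty, keeping the loss finite
        exactly at collapse while preserving divergence-like repulsion.
    clip_norm : global norm clip applied to each penalty gradient term.
    """

    alpha: float = 1.0
    ramp: Optional[tuple] = None
    s_max: float = 0.999
    clip_norm: float = 10.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0.9 < self.s_max < 1.0):
            raise ValueError("s_max must lie in (0.9, 1)")

    def alpha_at(self, iteration: int) -> float:
        if self.ramp is None:
            return self.alpha
        a0, a1, n = self.ramp
        if n <= 0 or iteration >= n:
            return a1
        return a0 + (a1 - a0) * iteration / n


def penalty(s: float, s_max: float = 0.999) -> float:
    """1/(1 - min(|S|, s_max)) - 1: zero at S=0, ~|S| to first order,
    monotone and >= S^2 on [0, s_max], divergent toward |S| = 1."""
    a = min(abs(s), s_max)
    return 1.0 / (1.0 - a) - 1.0


def penalty_deriv(s: float, s_max: float = 0.999) -> float:
    """d penalty / d|S| of the clamped penalty (0 beyond the clamp)."""
    a = abs(s)
    if a >= s_max:
        return 0.0
    return 1.0 / (1.0 - a) ** 2


@dataclass
class TrainingConfig:
    n_iterations: int = 2000
    batch_size: int = 2000
    decorrelation: int = 10       # chain steps between parameter updates
    burn_in: int = 200
    checkpoint_every: int = 100
    ema_decay: float = 0.99
    learning_rate: object = 0.05  # scalar or {group name: lr}
    lr_decay: Optional[float] = None  # timescale tau: lr_t = lr / (1 + t/tau)
    seed: int = 0
    eval_samples: int = 100_000   # exhaustive-evaluation sample count
    eval_thin: int = 10
    eval_burn_in: int = 1000      # nodal states equilibrate lobe masses slowly
    winsorize: bool = True
    divergence_window: int = 100
    divergence_rise: float = 1.0  # Ha; smoothed-energy rise that aborts


class TrainingDivergence(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class TrainingTrace:
    """Per-iteration statistics for every state, plus checkpoints."""

    energy: np.ndarray          # (T, n_states) raw batch means
    variance: np.ndarray        # (T, n_states) raw batch variances
    ema_energy: np.ndarray      # bias-corrected exponential moving averages
    ema_variance: np.ndarray
    overlaps: dict              # (i, j) -> (T,) per-iteration S_ij
    checkpoints: list           # [(iteration, [param vector per state])]
    acceptance: np.ndarray      # (T, n_states)
    penalty_terms: dict         # (i, j) -> (T,)

    @property
    def n_iterations(self):
        return self.energy.shape[0]

    @property
    def n_states(self):
        return self.energy.shape[1]

    def checkpoint_iterations(self):
        return np.array([it for it, _ in self.checkpoints])


@dataclass
class SpectrumResult:
    """Final estimates after exhaustive sampling of the trained states."""

    energies: list              # per state: ScalarEstimate
    pairs: list                 # per (i>j) pair: dict of results
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self):
        out = {
            "seed": self.seed,
            "metadata": self.metadata,
            "states": [
                {"energy": e.value, "se": e.se, "variance": e.variance,
                 "n_samples": e.n_eff}
                for e in self.energies
            ],
            "pairs": self.pairs,
        }
        return out


def smooth_statistics(values: np.ndarray, decay: float) -> np.ndarray:
    """Bias-corrected exponential moving average along axis 0.

    ema_t = (1-decay) sum_k decay^(t-k) x_k / (1 - decay^(t+1));
    decay -> 0 recovers the raw series, a constant series is unchanged.
    """
    if not (0.0 < decay < 1.0):
        raise ValueError("decay must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    acc = np.zeros(values.shape[1:]) if values.ndim > 1 else 0.0
    for t in range(values.shape[0]):
        acc = decay * acc + (1.0 - decay) * values[t]
        out[t] = acc / (1.0 - decay ** (t + 1))
    return out


def joint_loss(states, system, batches, cfg: PenaltyConfig, iteration: int = 0):
    """Total loss and per-term breakdown on the given batches.

    Returns (total, {"energies": [...], "penalties": {(i,j): value}}).
    Pairs run over the strict lower triangle i > j.
    """
    energies = [est.energy_estimate(s, system, b).value
                for s, b in zip(states, batches)]
    alpha = cfg.alpha_at(iteration)
    pens = {}
    for i in range(len(states)):
        for j in range(i):
            s_ij = est.overlap_estimate(states[i], states[j], batches[i], batches[j])
            pens[(i, j)] = penalty(s_ij.value, cfg.s_max)
    total = float(np.sum(energies)) + alpha * float(np.sum(list(pens.values()) or [0.0]))
    return total, {"energies": energies, "penalties": pens}


def gradient_assembly(states, system, batches, cfg: PenaltyConfig,
                      iteration: int = 0, winsorize: bool = True):
    """Per-state gradients with lower-state detachment.

    State 0 receives the pure energy gradient; state i adds
    alpha * penalty'(|S_ij|) * sgn(S_ij) * dS_ij/dtheta_i for each j < i,
    each penalty term norm-clipped.  Also returns the overlaps used.
    """
    alpha = cfg.alpha_at(iteration)
    grads = []
    overlaps = {}
    for i, (s_i, b_i) in enumerate(zip(states, batches)):
        g = est.grad_energy(s_i, system, b_i, winsorize=winsorize)
        for j in range(i):
            ov = est.overlap_estimate(s_i, states[j], b_i, batches[j])
            overlaps[(i, j)] = ov
            if alpha == 0.0 or ov.value == 0.0:
                continue
            g_ov, _ = est.grad_overlap(s_i, states[j], b_i, batches[j],
                                       detach_lower=True)
            term = alpha * penalty_deriv(ov.value, cfg.s_max) * np.sign(ov.value) * g_ov
            g = g + est.clip_gradient(term, cfg.clip_norm)
        grads.append(g)
    return grads, overlaps


def _lr_vector(state, learning_rate):
    lr = np.zeros(state.n_params)
    if isinstance(learning_rate, dict):
        default = learning_rate.get("default", 0.0)
        lr[:] = default
        for name, sl in state.param_groups().items():
            if name in learning_rate:
                lr[sl] = learning_rate[name]
    else:
        lr[:] = float(learning_rate)
    return lr


def train(states, system, tcfg: TrainingConfig, pcfg: PenaltyConfig,
          evaluate: bool = True):
    """Run the sample/estimate/step loop; return (trace, spectrum).

    Fully deterministic for a given seed in single-threaded mode: each
    state owns an independent RNG stream spawned from the master seed.
    """
    n = len(states)
    seeds = np.random.SeedSequence(tcfg.seed).spawn(n + 1)
    ensembles = [
        init_walkers(s, system, tcfg.batch_size, np.random.default_rng(ss),
                     burn_in=tcfg.burn_in)
        for s, ss in zip(states, seeds[:n])
    ]

    T = tcfg.n_iterations
    energy = np.zeros((T, n))
    variance = np.zeros((T, n))
    acceptance = np.zeros((T, n))
    overlaps_tr = {(i, j): np.zeros(T) for i in range(n) for j in range(i)}
    pen_tr = {(i, j): np.zeros(T) for i in range(n) for j in range(i)}
    checkpoints = [(0, [s.get_params().copy() for s in states])]
    ema_e = np.zeros(n)
    ema_v = np.zeros(n)
    ema_e_hist = np.zeros((T, n))
    ema_v_hist = np.zeros((T, n))
    beta = tcfg.ema_decay

    for t in range(T):
        batches = []
        for s, ens in zip(states, ensembles):
            run_steps(ens, s, tcfg.decorrelation)
            tune_step_size(ens)
            batches.append(ens.x.copy())
        for i, (s, b) in enumerate(zip(states, batches)):
            e = est.energy_estimate(s, system, b)
            energy[t, i] = e.value
            variance[t, i] = e.variance
            acceptance[t, i] = ensembles[i].acceptance
        grads, ovs = gradient_assembly(states, system, batches, pcfg,
                                       iteration=t, winsorize=tcfg.winsorize)
        for key, ov in ovs.items():
            overlaps_tr[key][t] = ov.value
            pen_tr[key][t] = penalty(ov.value, pcfg.s_max)
        decay = 1.0 if tcfg.lr_decay is None else 1.0 / (1.0 + t / tcfg.lr_decay)
        for s, ens, g in zip(states, ensembles, grads):
            lr = _lr_vector(s, tcfg.learning_rate) * decay
            new = s.get_params() - lr * np.where(s.trainable_mask(), g, 0.0)
            s.set_params(new)
            resync(ens, s)
        ema_e = beta * ema_e + (1 - beta) * energy[t]
        ema_v = beta * ema_v + (1 - beta) * variance[t]
        corr = 1.0 - beta ** (t + 1)
        ema_e_hist[t] = ema_e / corr
        ema_v_hist[t] = ema_v / corr
        if (t + 1) % tcfg.checkpoint_every == 0:
            checkpoints.append((t + 1, [s.get_params().copy() for s in states]))
        w = tcfg.divergence_window
        if t >= w:
            rise = ema_e_hist[t] - ema_e_hist[t - w]
            if np.any(rise > tcfg.divergence_rise):
                trace = TrainingTrace(energy[: t + 1], variance[: t + 1],
                                      ema_e_hist[: t + 1], ema_v_hist[: t + 1],
                                      {k: v[: t + 1] for k, v in overlaps_tr.items()},
                                      checkpoints, acceptance[: t + 1],
                                      {k: v[: t + 1] for k, v in pen_tr.items()})
                raise TrainingDivergence(
                    f"smoothed energy rose by {float(np.max(rise)):.3f} Ha "
                    f"over {w} iterations", trace)

    if checkpoints[-1][0] != T:
        checkpoints.append((T, [s.get_params().copy() for s in states]))
    trace = TrainingTrace(energy, variance, ema_e_hist, ema_v_hist,
                          overlaps_tr, checkpoints, acceptance, pen_tr)
    spectrum = None
    if evaluate:
        spectrum = evaluate_states(
            states, system, trace, tcfg,
            rng=np.random.default_rng(seeds[n]),
        )
    return trace, spectrum


def evaluate_states(states, system, trace, tcfg: TrainingConfig, rng=None,
                    compute_tdm: bool = True) -> SpectrumResult:
    """Exhaustive fixed-parameter evaluation of the trained states.

    Long decorrelated sampling per state; energies with jackknife block
    errors, all pairwise overlaps, transition dipoles and oscillator
    strengths, and variance-matched excitation energies obtained by
    re-evaluating the matched checkpoints.
    """
    rng = rng or np.random.default_rng(0)
    n = len(states)
    samples = []
    energies = []
    for s in states:
        ens = init_walkers(s, system, min(tcfg.batch_size, 2000),
                           np.random.default_rng(rng.integers(2**31)),
                           burn_in=max(tcfg.burn_in, tcfg.eval_burn_in))
        x = sample_batches(ens, s, tcfg.eval_samples, thin=tcfg.eval_thin)
        samples.append(x)
        e = est.energy_estimate(s, system, x)
        # jackknife SE over blocks (samples are correlated across the chain)
        from .estimators import _block_jackknife
        from .systems import local_energy
        eloc = local_energy(s, system, x, check=False)
        eloc = eloc[np.isfinite(eloc)]
        se = _block_jackknife(lambda a: float(np.mean(a)), (eloc,))
        energies.append(est.ScalarEstimate(e.value, se, e.n_eff, e.variance))

    pairs = []
    for i in range(n):
        for j in range(i):
            ov = est.overlap_estimate(states[i], states[j], samples[i], samples[j])
            de = energies[i].value - energies[j].value
            de_se = math.hypot(energies[i].se, energies[j].se)
            matched = variance_match(trace, j, i)
            if matched["matched_iterations"] == (trace.n_iterations,
                                                 trace.n_iterations):
                de_m = de
            else:
                de_m = _matched_delta_e(states, system, trace, tcfg, i, j,
                                        matched, rng)
            entry = {
                "i": i, "j": j,
                "delta_e": de, "delta_e_se": de_se,
                "delta_e_matched": de_m,
                "variance_matched": matched["matched"],
                "matched_iterations": matched["matched_iterations"],
                "overlap": ov.value, "overlap_se": ov.se,
                "overlap_cap_rate": ov.cap_rate,
            }
            if compute_tdm:
                tm = est.transition_dipole(states[i], states[j],
                                           samples[i], samples[j], delta_e=abs(de))
                entry["tdm"] = tm.d.tolist()
                entry["tdm_se"] = tm.d_se.tolist()
                entry["d2"] = tm.d2
                entry["oscillator_strength"] = tm.oscillator_strength
            pairs.append(entry)
    return SpectrumResult(energies=energies, pairs=pairs, seed=tcfg.seed)


def _matched_delta_e(states, system, trace, tcfg, i, j, matched, rng):
    """Excitation energy from re-evaluated matched checkpoints."""
    it_j, it_i = matched["matched_iterations"]
    vals = {}
    for state_idx, it in ((j, it_j), (i, it_i)):
        s = states[state_idx]
        saved = s.get_params().copy()
        params = _checkpoint_params(trace, it)[state_idx]
        s.set_params(params)
        ens = init_walkers(s, system, min(tcfg.batch_size, 2000),
                           np.random.default_rng(rng.integers(2**31)),
                           burn_in=max(tcfg.burn_in, tcfg.eval_burn_in))
        x = sample_batches(ens, s, max(tcfg.eval_samples // 2, 1000),
                           thin=tcfg.eval_thin)
        vals[state_idx] = est.energy_estimate(s, system, x).value
        s.set_params(saved)
    return vals[i] - vals[j]


def _checkpoint_params(trace, iteration):
    for it, params in trace.checkpoints:
        if it == iteration:
            return params
    raise KeyError(f"no checkpoint at iteration {iteration}")


def variance_match(trace: TrainingTrace, state_lo: int, state_hi: int) -> dict:
    """Select checkpoints with matched smoothed energy variance.

    The state with the higher *final* smoothed variance keeps its final
    checkpoint; the other state is rewound to the checkpointed iteration
    whose smoothed variance is closest to that target (ties resolved to
    the latest iteration).  If the target lies below the rewound state's
    entire series, both final checkpoints are kept and the pair is flagged
    unmatched.

    Returns {"matched_iterations": (iter_lo, iter_hi), "matched": bool}.
    """
    iters = trace.checkpoint_iterations()
    iters = iters[iters > 0]  # iteration 0 has no smoothed statistics
    T = trace.n_iterations
    final_var = trace.ema_variance[-1]
    v_lo, v_hi = final_var[state_lo], final_var[state_hi]
    if v_lo == v_hi:
        return {"matched_iterations": (T, T), "matched": True}
    rewind_state = state_lo if v_lo < v_hi else state_hi
    target = max(v_lo, v_hi)
    series = trace.ema_variance[iters - 1, rewind_state]
    if target > np.max(series):
        # the rewound state was never as noisy as the target: no
        # meaningful match exists, keep the final checkpoints
        return {"matched_iterations": (T, T), "matched": False}
    dist = np.abs(series - target)
    best = np.max(np.where(dist == np.min(dist))[0])  # ties -> latest
    it_rewind = int(iters[best])
    if rewind_state == state_lo:
        return {"matched_iterations": (it_rewind, T), "matched": True}
    return {"matched_iterations": (T, it_rewind), "matched": True}
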