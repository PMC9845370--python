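"""Penalty loss, gradient assembly, EMA smoothing, variance matching."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from excitedvmc import estimators as est
from excitedvmc.states import HarmonicEigenstate, LinearCombination, PolyGaussian1D
from excitedvmc.systems import HarmonicPotential, ModelSystem
from excitedvmc.training import (
    PenaltyConfig,
    TrainingConfig,
    TrainingDivergence,
    TrainingTrace,
    gradient_assembly,
    joint_loss,
    penalty,
    penalty_deriv,
    smooth_statistics,
    train,
    variance_match,
)


class TestPenalty:
    def test_zero_at_orthogonality(self):
        assert penalty(0.0) == 0.0

    def test_half_overlap_value(self):
        assert penalty(0.5) == pytest.approx(1.0)

    def test_first_order_linearity(self):
        # near S = 0 the penalty is S + S^2 + S^3 + ...; the deviation
        # from linearity is S^2/(1-S), within the 2 S^2 Taylor bound
        s = 1e-3
        assert abs(penalty(s) - s) == pytest.approx(s**2 / (1 - s), rel=1e-9)
        assert abs(penalty(s) - s) <= 2 * s**2

    @given(st.floats(0.0, 0.5))
    def test_linear_approximation_bound(self, s):
        assert abs(penalty(s) - s) <= 2 * s**2 + 1e-15

    @given(st.floats(0.0, 0.999))
    def test_lower_bounded_by_s_squared(self, s):
        assert penalty(s) >= s**2 - 1e-15

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_monotone_in_magnitude(self, a, b):
        if abs(a) <= abs(b):
            assert penalty(a) <= penalty(b) + 1e-15

    def test_clamp_keeps_loss_finite_at_collapse(self):
        assert np.isfinite(penalty(1.0))
        assert penalty(1.0) == penalty(0.999)

    def test_derivative_matches_fd(self):
        for s in (0.1, 0.4, 0.8):
            fd = (penalty(s + 1e-7) - penalty(s - 1e-7)) / 2e-7
            assert penalty_deriv(s) == pytest.approx(fd, rel=1e-5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PenaltyConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            PenaltyConfig(s_max=0.5)

    def test_alpha_ramp(self):
        cfg = PenaltyConfig(alpha=1.0, ramp=(0.5, 2.0, 100))
        assert cfg.alpha_at(0) == 0.5
        assert cfg.alpha_at(50) == pytest.approx(1.25)
        assert cfg.alpha_at(1000) == 2.0


class TestJointLoss:
    def _setup(self, rng, n):
        system = ModelSystem(1, 1, HarmonicPotential(1.0))
        states = [
            LinearCombination(
                [HarmonicEigenstate(0), HarmonicEigenstate(1), HarmonicEigenstate(2)],
                np.eye(3)[k] + 0.1 * rng.normal(size=3),
            )
            for k in range(n)
        ]
        batches = [rng.normal(size=(500, 1, 1)) for _ in range(n)]
        return system, states, batches

    def test_alpha_zero_reduces_to_energy_sum(self, rng):
        system, states, batches = self._setup(rng, 2)
        total, parts = joint_loss(states, system, batches, PenaltyConfig(alpha=0.0))
        assert total == pytest.approx(np.sum(parts["energies"]))

    def test_single_state_is_ground_state_loss(self, rng):
        system, states, batches = self._setup(rng, 1)
        total, parts = joint_loss(states, system, batches, PenaltyConfig())
        assert parts["penalties"] == {}
        e = est.energy_estimate(states[0], system, batches[0])
        assert total == pytest.approx(e.value)

    def test_three_states_three_pairs(self, rng):
        system, states, batches = self._setup(rng, 3)
        _, parts = joint_loss(states, system, batches, PenaltyConfig())
        assert set(parts["penalties"]) == {(1, 0), (2, 0), (2, 1)}


class TestGradientAssembly:
    def _setup(self, rng, n):
        system = ModelSystem(1, 1, HarmonicPotential(1.0))
        states = [
            LinearCombination(
                [HarmonicEigenstate(0), HarmonicEigenstate(1), HarmonicEigenstate(2)],
                np.eye(3)[k] + 0.1 * rng.normal(size=3),
            )
            for k in range(n)
        ]
        batches = [rng.normal(size=(500, 1, 1)) for _ in range(n)]
        return system, states, batches

    def test_ground_state_unconstrained(self, rng):
        # state 0's gradient must be bit-identical to a pure energy run
        system, states, batches = self._setup(rng, 2)
        grads, _ = gradient_assembly(states, system, batches,
                                     PenaltyConfig(alpha=1.0))
        pure = est.grad_energy(states[0], system, batches[0])
        np.testing.assert_array_equal(grads[0], pure)

    def test_state_two_receives_two_penalty_terms(self, rng):
        system, states, batches = self._setup(rng, 3)
        cfg = PenaltyConfig(alpha=1.0)
        grads, overlaps = gradient_assembly(states, system, batches, cfg)
        assert {(1, 0), (2, 0), (2, 1)} == set(overlaps)
        # reconstruct state 2's gradient from its parts
        g = est.grad_energy(states[2], system, batches[2])
        for j in (0, 1):
            ov = overlaps[(2, j)]
            g_ov, _ = est.grad_overlap(states[2], states[j], batches[2],
                                       batches[j], detach_lower=True)
            term = penalty_deriv(ov.value) * np.sign(ov.value) * g_ov
            g = g + est.clip_gradient(term, cfg.clip_norm)
        np.testing.assert_allclose(grads[2], g, atol=1e-12)

    def test_alpha_zero_drops_penalties(self, rng):
        system, states, batches = self._setup(rng, 2)
        grads, _ = gradient_assembly(states, system, batches,
                                     PenaltyConfig(alpha=0.0))
        pure = est.grad_energy(states[1], system, batches[1])
        np.testing.assert_array_equal(grads[1], pure)


class TestSmoothStatistics:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(smooth_statistics(x, 0.99), 3.7)

    def test_small_decay_recovers_raw(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_allclose(smooth_statistics(x, 1e-12), x)

    def test_step_response_closed_form(self):
        # series jumps 0 -> 1 at iteration k; smoothed response follows
        # 1 - decay^m (after bias correction) m steps later
        k, decay, T = 10, 0.99, 60
        x = np.zeros(T)
        x[k:] = 1.0
        s = smooth_statistics(x, decay)
        for m in (1, 10, 40):
            t = k + m - 1
            expected = (1 - decay**m) / (1 - decay ** (t + 1))
            assert s[t] == pytest.approx(expected, rel=1e-12)

    def test_invalid_decay(self):
        with pytest.raises(ValueError):
            smooth_statistics(np.ones(3), 1.0)


def synthetic_trace(var_series, checkpoint_every=10):
    """Build a TrainingTrace with prescribed smoothed variance series."""
    var = np.asarray(var_series, dtype=float)
    T, n = var.shape
    iters = list(range(0, T + 1, checkpoint_every))
    if iters[-1] != T:
        iters.append(T)
    return TrainingTrace(
        energy=np.zeros((T, n)),
        variance=var,
        ema_energy=np.zeros((T, n)),
        ema_variance=var,  # treat the series as already smoothed
        overlaps={},
        checkpoints=[(it, [np.zeros(1)] * n) for it in iters],
        acceptance=np.zeros((T, n)),
        penalty_terms={},
    )


class TestVarianceMatch:
    def test_equal_final_variances_keep_finals(self):
        var = np.stack([np.linspace(1, 0.2, 100)] * 2, axis=1)
        trace = synthetic_trace(var)
        m = variance_match(trace, 0, 1)
        assert m["matched_iterations"] == (100, 100)
        assert m["matched"]

    def test_matches_brute_force_argmin(self):
        # strictly decreasing ground-state variance, noisier excited state
        rng = np.random.default_rng(5)
        v0 = np.linspace(1.0, 0.05, 200)
        v1 = np.linspace(1.2, 0.4, 200)
        trace = synthetic_trace(np.stack([v0, v1], axis=1))
        m = variance_match(trace, 0, 1)
        target = v1[-1]
        iters = trace.checkpoint_iterations()
        iters = iters[iters > 0]
        dists = np.abs(v0[iters - 1] - target)
        best = iters[np.max(np.where(dists == dists.min())[0])]
        assert m["matched_iterations"] == (int(best), 200)

    def test_rewinds_the_lower_variance_state(self):
        # the state with the *higher* final variance keeps its final
        # checkpoint; the better-converged one is rewound
        v0 = np.linspace(1.0, 0.05, 100)   # ground: converges well
        v1 = np.linspace(1.0, 0.5, 100)    # excited: stays noisy
        trace = synthetic_trace(np.stack([v0, v1], axis=1))
        m = variance_match(trace, 0, 1)
        lo_it, hi_it = m["matched_iterations"]
        assert hi_it == 100 and lo_it < 100

    def test_ties_resolve_to_latest(self):
        v0 = np.concatenate([np.full(50, 0.5), np.full(50, 0.3)])
        v1 = np.full(100, 0.5)
        trace = synthetic_trace(np.stack([v0, v1], axis=1))
        m = variance_match(trace, 0, 1)
        assert m["matched_iterations"][0] == 50  # latest checkpoint at 0.5

    def test_unreachable_target_falls_back_flagged(self):
        v0 = np.full(100, 0.01)           # never as noisy as the target
        v1 = np.full(100, 1.0)
        trace = synthetic_trace(np.stack([v0, v1], axis=1))
        m = variance_match(trace, 0, 1)
        assert m["matched_iterations"] == (100, 100)
        assert not m["matched"]


class TestTrainLoop:
    def _states(self, n=2, width=1.25):
        return [
            PolyGaussian1D(np.eye(4)[k], log_width=np.log(width))
            for k in range(n)
        ]

    def test_bit_exact_reproducibility(self, harmonic):
        cfgs = dict(
            n_iterations=20, batch_size=200, decorrelation=2, burn_in=20,
            learning_rate=0.02, seed=42, eval_samples=2000, eval_burn_in=50,
        )
        results = []
        for _ in range(2):
            states = self._states()
            trace, spec = train(states, harmonic, TrainingConfig(**cfgs),
                                PenaltyConfig(alpha=1.0))
            results.append((trace, spec, [s.get_params() for s in states]))
        t1, s1, p1 = results[0]
        t2, s2, p2 = results[1]
        np.testing.assert_array_equal(t1.energy, t2.energy)
        np.testing.assert_array_equal(t1.variance, t2.variance)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)
        assert s1.energies[0].value == s2.energies[0].value
        assert s1.pairs[0]["overlap"] == s2.pairs[0]["overlap"]

    def test_checkpoints_restore_bit_exact(self, harmonic):
        states = self._states()
        tcfg = TrainingConfig(n_iterations=30, batch_size=100, decorrelation=2,
                              burn_in=20, checkpoint_every=10, seed=7,
                              eval_samples=1000, eval_burn_in=50)
        trace, _ = train(states, harmonic, tcfg, PenaltyConfig())
        it, params = trace.checkpoints[-1]
        assert it == 30
        for s, p in zip(states, params):
            np.testing.assert_array_equal(s.get_params(), p)

    def test_divergence_guard_aborts_with_trace(self, harmonic):
        # an absurd learning rate forces the smoothed energy upward
        states = self._states()
        tcfg = TrainingConfig(n_iterations=400, batch_size=100, decorrelation=1,
                              burn_in=20, learning_rate=5.0, seed=3,
                              divergence_window=50, ema_decay=0.9)
        with pytest.raises(TrainingDivergence) as exc:
            train(states, harmonic, tcfg, PenaltyConfig())
        assert isinstance(exc.value.trace, TrainingTrace)

    def test_frozen_groups_never_move(self, harmonic):
        states = [
            PolyGaussian1D(np.eye(3)[k], log_width=0.1, train_width=False)
            for k in range(2)
        ]
        t0 = [s.t for s in states]
        tcfg = TrainingConfig(n_iterations=15, batch_size=100, decorrelation=2,
                              burn_in=20, seed=1, eval_samples=1000,
                              eval_burn_in=50)
        train(states, harmonic, tcfg, PenaltyConfig(), evaluate=False)
        assert [s.t for s in states] == t0


class TestPenaltyLandscape:
    def test_minimum_at_orthogonality_for_sufficient_alpha(self, harmonic):
        """Brute-force sweep of loss(eps) over the mixture family.

        With the exact two-state mixture, loss(eps) = (1-eps) E1 + eps E0
        + alpha * penalty(sqrt(eps)); for alpha = 0 the optimum collapses
        to eps = 1 (the ground state), while any alpha above the energy
        gap puts the global optimum at eps = 0.
        """
        e0, e1 = 0.5, 1.5
        eps = np.linspace(0, 1, 2001)

        def loss(alpha):
            return (1 - eps) * e1 + eps * e0 + alpha * np.array(
                [penalty(np.sqrt(e)) for e in eps]
            )

        assert eps[np.argmin(loss(0.0))] == 1.0
        assert eps[np.argmin(loss(1.5))] == 0.0
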