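"""Monte Carlo estimators against closed forms, quadrature and FD oracles."""

import numpy as np
import pytest

from excitedvmc import estimators as est
from excitedvmc.estimators import (
    DipoleComponent,
    HamiltonianOperator,
    Identity,
    Multiplicative,
    _cap_ratio,
    _log_ratio,
    grad_mixed_observable,
)
from excitedvmc.oracles import GridSpec, make_mixture, quadrature_observable
from excitedvmc.sampler import init_walkers, sample_batches
from excitedvmc.states import (
    BoxEigenstate,
    ExpSlater,
    HarmonicEigenstate,
    Hydrogenic1s,
    Hydrogenic2pz,
    LinearCombination,
    NormalizationWrapper,
    PolyGaussian1D,
)
from excitedvmc.systems import BoxPotential, ModelSystem


def draw(psi, system, n, seed, B=2000, thin=5, burn_in=200):
    ens = init_walkers(psi, system, min(B, n), seed=seed, burn_in=burn_in)
    return sample_batches(ens, psi, n, thin=thin)


class TestEnergyEstimate:
    def test_eigenstate_zero_variance(self, harmonic, rng):
        x = rng.normal(size=(2000, 1, 1))
        e = est.energy_estimate(HarmonicEigenstate(0), harmonic, x)
        assert e.value == pytest.approx(0.5, abs=1e-12)
        assert e.se < 1e-10 and e.variance < 1e-10

    def test_exp_slater_variational_energy(self, hydrogen):
        # E(alpha) = alpha^2/2 - alpha = -0.48 at alpha = 0.8
        psi = ExpSlater(0.8)
        x = draw(psi, hydrogen, 20000, seed=4)
        e = est.energy_estimate(psi, hydrogen, x)
        se = max(e.se * np.sqrt(10), 1e-6)  # correlation margin
        assert abs(e.value - (-0.48)) < 3 * se

    def test_variational_bound_on_box(self, rng):
        box = ModelSystem(1, 1, BoxPotential(1.0))
        psi = BoxEigenstate(1)
        x = draw(psi, box, 5000, seed=5)
        e = est.energy_estimate(psi, box, x)
        assert e.value >= np.pi**2 / 2 - 3 * max(e.se, 1e-9) - 1e-9


class TestOverlapEstimate:
    def test_scale_invariance_bit_level(self, harmonic, rng):
        s0 = HarmonicEigenstate(0)
        mix = LinearCombination([HarmonicEigenstate(1), s0], [0.9, 0.44])
        scaled = NormalizationWrapper(mix, c=np.log(3.0))
        x0 = rng.normal(size=(4000, 1, 1))
        xm = rng.normal(size=(4000, 1, 1)) * 1.3
        a = est.overlap_estimate(s0, mix, x0, xm)
        b = est.overlap_estimate(s0, scaled, x0, xm)
        assert a.value == b.value  # norm factors cancel exactly in log form

    def test_scaled_duplicate_state_unit_overlap(self, rng):
        # psi_j = 3 * psi_i (different objects): the ratio is exactly 3
        # pointwise, its reverse exactly 1/3, so S = 1 to round-off
        mix = LinearCombination([HarmonicEigenstate(1), HarmonicEigenstate(0)],
                                [0.9, 0.44])
        scaled = NormalizationWrapper(mix, c=np.log(3.0))
        x_i = rng.normal(size=(2000, 1, 1))
        x_j = rng.normal(size=(2000, 1, 1)) * 1.2
        ov = est.overlap_estimate(mix, scaled, x_i, x_j)
        assert ov.value == pytest.approx(1.0, abs=1e-10)

    def test_self_overlap_exactly_one(self, rng):
        s0 = HarmonicEigenstate(0)
        x = rng.normal(size=(100, 1, 1))
        ov = est.overlap_estimate(s0, s0, x, x)
        assert ov.value == 1.0 and ov.se == 0.0

    def test_mixture_quarter_overlap(self, harmonic):
        fix = make_mixture(0.25, HarmonicEigenstate(0), HarmonicEigenstate(1))
        x0 = draw(fix.state0, harmonic, 10000, seed=1)
        xm = draw(fix.mixed, harmonic, 10000, seed=2)
        ov = est.overlap_estimate(fix.state0, fix.mixed, x0, xm)
        assert abs(ov.value - 0.5) <= 3 * ov.se

    def test_opposite_parity_states_orthogonal(self, hydrogen):
        s1, p1 = Hydrogenic1s(), Hydrogenic2pz()
        x1 = draw(s1, hydrogen, 8000, seed=3)
        xp = draw(p1, hydrogen, 8000, seed=4)
        ov = est.overlap_estimate(s1, p1, x1, xp)
        assert abs(ov.value) <= 3 * max(ov.se, 1e-3)

    def test_symmetric_under_argument_swap(self, harmonic, rng):
        s0 = HarmonicEigenstate(0)
        mix = LinearCombination([HarmonicEigenstate(1), s0], [0.9, 0.44])
        x0 = rng.normal(size=(3000, 1, 1))
        xm = rng.normal(size=(3000, 1, 1))
        a = est.overlap_estimate(s0, mix, x0, xm)
        b = est.overlap_estimate(mix, s0, xm, x0)
        assert a.value == pytest.approx(b.value, abs=1e-14)


class TestMixedObservable:
    def test_identity_reduces_to_overlap_bit_exact(self, rng):
        s0 = HarmonicEigenstate(0)
        mix = LinearCombination([HarmonicEigenstate(1), s0], [0.9, 0.44])
        x0 = rng.normal(size=(3000, 1, 1))
        xm = rng.normal(size=(3000, 1, 1))
        a = est.overlap_estimate(s0, mix, x0, xm)
        b = est.mixed_observable(Identity(), s0, mix, x0, xm)
        assert a.value == b.value and a.se == b.se

    def test_parity_selection_rule_same_state(self, hydrogen):
        psi = Hydrogenic1s()
        x = draw(psi, hydrogen, 8000, seed=6)
        op = Multiplicative(lambda p: p[:, 0, 0])
        m = est.mixed_observable(op, psi, psi, x, x.copy())
        assert abs(m.value) <= 3 * max(m.se, 1e-3)

    def test_harmonic_ladder_element(self, harmonic):
        # <0|x|1> = 1/sqrt(2 omega)
        s0, s1 = HarmonicEigenstate(0), HarmonicEigenstate(1)
        x0 = draw(s0, harmonic, 10000, seed=7)
        x1 = draw(s1, harmonic, 10000, seed=8)
        op = Multiplicative(lambda p: p[:, 0, 0])
        m = est.mixed_observable(op, s0, s1, x0, x1)
        assert abs(abs(m.value) - 1 / np.sqrt(2)) <= 3 * m.se


class TestTransitionDipole:
    def test_same_state_centrosymmetric_zero(self, harmonic):
        s1 = HarmonicEigenstate(1)
        x = draw(s1, harmonic, 8000, seed=9)
        tm = est.transition_dipole(s1, s1, x, x.copy(), delta_e=0.0)
        assert np.all(np.abs(tm.d) <= 3 * np.maximum(tm.d_se, 1e-3))

    def test_harmonic_zero_to_one(self, harmonic):
        s0, s1 = HarmonicEigenstate(0), HarmonicEigenstate(1)
        x0 = draw(s0, harmonic, 10000, seed=10)
        x1 = draw(s1, harmonic, 10000, seed=11)
        tm = est.transition_dipole(s0, s1, x0, x1, delta_e=1.0)
        assert abs(abs(tm.d[0]) - 1 / np.sqrt(2)) <= 3 * tm.d_se[0]
        assert tm.d2 == pytest.approx(np.sum(tm.d**2))

    def test_same_parity_selection_rule(self, harmonic):
        s0, s2 = HarmonicEigenstate(0), HarmonicEigenstate(2)
        x0 = draw(s0, harmonic, 8000, seed=12)
        x2 = draw(s2, harmonic, 8000, seed=13)
        tm = est.transition_dipole(s0, s2, x0, x2, delta_e=2.0)
        assert abs(tm.d[0]) <= 3 * max(tm.d_se[0], 1e-3)


class TestOscillatorStrength:
    def test_arithmetic(self):
        assert est.oscillator_strength(1.0, 3.0) == pytest.approx(2.0)
        assert est.oscillator_strength(0.7, 0.0) == 0.0

    def test_harmonic_zero_to_one_third(self, harmonic):
        s0, s1 = HarmonicEigenstate(0), HarmonicEigenstate(1)
        x0 = draw(s0, harmonic, 10000, seed=14)
        x1 = draw(s1, harmonic, 10000, seed=15)
        tm = est.transition_dipole(s0, s1, x0, x1, delta_e=1.0)
        # d^2 = 1/2, dE = 1 -> f = 1/3; propagate the d error bar
        f_se = (2.0 / 3.0) * 2 * abs(tm.d[0]) * tm.d_se[0]
        assert abs(tm.oscillator_strength - 1.0 / 3.0) <= 3 * f_se


class TestGradEnergy:
    def test_eigenstate_gradient_vanishes(self, harmonic, rng):
        psi = PolyGaussian1D([1.0, 0, 0], log_width=0.0)
        x = rng.normal(0, np.sqrt(0.5), size=(3000, 1, 1))
        g = est.grad_energy(psi, harmonic, x)
        assert np.linalg.norm(g) < 1e-8

    def test_exp_slater_closed_form(self, hydrogen):
        # dE/dalpha = alpha - 1 = -0.2 at alpha = 0.8
        psi = ExpSlater(0.8)
        x = draw(psi, hydrogen, 40000, seed=16)
        g = est.grad_energy(psi, hydrogen, x, winsorize=False)
        # per-sample variance of the gradient estimator, with margin
        se = 0.02
        assert abs(g[0] - (-0.2)) < 3 * se

    def test_pure_normalization_parameter_zero_gradient(self, harmonic, rng):
        psi = NormalizationWrapper(HarmonicEigenstate(0), c=0.3)
        x = rng.normal(0, np.sqrt(0.5), size=(2000, 1, 1))
        g = est.grad_energy(psi, harmonic, x)
        assert g[-1] == 0.0  # centered covariance with constant dln|psi|

    def test_frozen_groups_zeroed(self, harmonic, rng):
        psi = PolyGaussian1D([0.9, 0.1, 0.05], log_width=0.1, train_width=False)
        x = rng.normal(size=(1000, 1, 1))
        g = est.grad_energy(psi, harmonic, x)
        assert g[-1] == 0.0


class TestGradOverlap:
    def _pair(self, harmonic):
        a = LinearCombination([HarmonicEigenstate(0), HarmonicEigenstate(1)],
                              [0.9, 0.3])
        b = LinearCombination([HarmonicEigenstate(0), HarmonicEigenstate(1)],
                              [0.2, 0.95])
        xa = draw(a, harmonic, 4000, seed=17)
        xb = draw(b, harmonic, 4000, seed=18)
        return a, b, xa, xb

    def test_matches_fd_of_reweighted_estimator(self, harmonic):
        """Frozen-batch finite differences (common random numbers).

        The score-function gradient is the exact derivative of the
        self-normalized reweighted overlap estimator, so central FD in the
        sampling weights must agree to ~1e-4 relative.
        """
        a, b, xa, xb = self._pair(harmonic)
        gi, gj = est.grad_overlap(a, b, xa, xb, detach_lower=False)
        Ra, _ = _cap_ratio(_log_ratio(b, a, xa))
        Rb, _ = _cap_ratio(_log_ratio(a, b, xb))
        la0 = a.sign_log(xa)[1]
        th0 = a.get_params().copy()

        def s_of(t):
            a.set_params(t)
            w = np.exp(2 * (a.sign_log(xa)[1] - la0))
            a.set_params(th0)
            mi = np.sum(w * Ra) / np.sum(w)
            mj = np.mean(Rb)
            return np.sign(mi) * np.sqrt(mi * mj)

        h = 1e-6
        for k in range(th0.size):
            tp, tm = th0.copy(), th0.copy()
            tp[k] += h
            tm[k] -= h
            fd = (s_of(tp) - s_of(tm)) / (2 * h)
            assert abs(gi[k] - fd) <= 1e-4 * max(abs(fd), 1e-8)

    def test_detach_lower_returns_only_upper_gradient(self, harmonic):
        a, b, xa, xb = self._pair(harmonic)
        gi, gj = est.grad_overlap(a, b, xa, xb, detach_lower=True)
        assert gj is None and gi.shape == (2,)

    def test_hamiltonian_diagonal_recovers_energy_gradient(self, harmonic, rng):
        psi = PolyGaussian1D([0.8, 0.3, -0.2], log_width=0.15)
        x = draw(psi, harmonic, 3000, seed=19)
        op = HamiltonianOperator(harmonic)
        g_mixed, _ = grad_mixed_observable(op, psi, psi, x, x)
        g_energy = est.grad_energy(psi, harmonic, x)
        e = est.energy_estimate(psi, harmonic, x).value
        np.testing.assert_array_equal(g_mixed, np.sign(e) * g_energy)

    def test_pure_normalization_parameter_zero_in_expectation(self, harmonic):
        a = NormalizationWrapper(
            LinearCombination([HarmonicEigenstate(0), HarmonicEigenstate(1)],
                              [0.9, 0.3], trainable=False), c=0.2)
        b = LinearCombination([HarmonicEigenstate(0), HarmonicEigenstate(1)],
                              [0.2, 0.95])
        xa = draw(a, harmonic, 30000, seed=20)
        xb = draw(b, harmonic, 30000, seed=21)
        gi, _ = est.grad_overlap(a, b, xa, xb)
        assert abs(gi[-1]) < 0.02  # vanishes only in expectation

    def test_near_zero_overlap_gradient_zeroed(self, harmonic):
        s0, s1 = HarmonicEigenstate(0), HarmonicEigenstate(1)
        a = LinearCombination([s0, s1], [1.0, 0.0])
        b = LinearCombination([s0, s1], [0.0, 1.0])
        xa = draw(a, harmonic, 3000, seed=22)
        xb = draw(b, harmonic, 3000, seed=23)
        gi, gj = est.grad_overlap(a, b, xa, xb, detach_lower=False)
        ov = est.overlap_estimate(a, b, xa, xb)
        if not ov.signs_agree or abs(ov.value) < 1e-8:
            assert np.all(gi == 0.0)


class TestQuadratureEquivalence:
    def test_overlap_and_dipole_match_grid_quadrature(self, harmonic):
        """Monte Carlo estimates vs dense-grid integrals, random pairs.

        Nodal 1D states need long equilibration: the relative probability
        mass of the lobes separated by a node mixes slowly, so frozen-state
        estimation uses a long burn-in.
        """
        rng = np.random.default_rng(100)
        grid = GridSpec(10.0, 4001)
        for trial in range(5):
            a = PolyGaussian1D(rng.normal(size=3), log_width=0.2 * rng.normal())
            b = PolyGaussian1D(rng.normal(size=3), log_width=0.2 * rng.normal())
            xa = draw(a, harmonic, 6000, seed=200 + trial, burn_in=3000)
            xb = draw(b, harmonic, 6000, seed=300 + trial, burn_in=3000)
            ov = est.overlap_estimate(a, b, xa, xb)
            exact = quadrature_observable(None, a, b, grid)
            assert abs(abs(ov.value) - abs(exact)) <= 3 * max(ov.se, 5e-3)
            m = est.mixed_observable(DipoleComponent(0), a, b, xa, xb)
            exact_d = quadrature_observable(lambda p: -p[:, 0, 0], a, b, grid)
            assert abs(abs(m.value) - abs(exact_d)) <= 3 * max(m.se, 5e-3)


class TestRatioCapping:
    def test_cap_rate_reported(self, rng):
        r = rng.standard_cauchy(5000)
        capped, rate = _cap_ratio(r)
        assert 0 < rate <= 0.002
        assert np.max(np.abs(capped)) <= np.quantile(np.abs(r), 0.999)
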