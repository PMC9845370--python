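"""Closed-form eigenstates and simple parametrized trial states.

These serve three roles: exact references (zero-variance checks, mixture
fixtures), initial states for the solvable-system baselines, and small
trainable ansatzes for the 1D spectrum-recovery experiments.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite import hermval, hermder

from .wavefunction import WaveFunction, batchify

__all__ = [
    "Hydrogenic1s",
    "Hydrogenic2s",
    "Hydrogenic2pz",
    "HarmonicEigenstate",
    "BoxEigenstate",
    "ExpSlater",
    "PolyGaussian1D",
    "LinearCombination",
    "NormalizationWrapper",
]


class Hydrogenic1s(WaveFunction):
    """psi = (Z^3/pi)^(1/2) exp(-Z r); E = -Z^2/2."""

    n_particles, d = 1, 3

    def __init__(self, z: float = 1.0):
        self.z = float(z)
        self.energy = -0.5 * self.z**2
        self._lognorm = 0.5 * math.log(self.z**3 / math.pi)

    def _r(self, x):
        xb, _ = batchify(x, 1, 3)
        return xb, np.linalg.norm(xb[:, 0, :], axis=-1)

    def sign_log(self, x):
        xb, r = self._r(x)
        return np.ones(xb.shape[0]), self._lognorm - self.z * r

    def grad_log(self, x):
        xb, r = self._r(x)
        return -self.z * xb / r[:, None, None]

    def lap_log(self, x):
        _, r = self._r(x)
        return -2.0 * self.z / r


class Hydrogenic2s(WaveFunction):
    """psi = (Z^3/(32 pi))^(1/2) (2 - Z r) exp(-Z r / 2); E = -Z^2/8."""

    n_particles, d = 1, 3

    def __init__(self, z: float = 1.0):
        self.z = float(z)
        self.energy = -self.z**2 / 8.0
        self._lognorm = 0.5 * math.log(self.z**3 / (32.0 * math.pi))

    def _r(self, x):
        xb, _ = batchify(x, 1, 3)
        return xb, np.linalg.norm(xb[:, 0, :], axis=-1)

    def sign_log(self, x):
        xb, r = self._r(x)
        p = 2.0 - self.z * r
        sign = np.sign(p)
        with np.errstate(divide="ignore"):
            log = self._lognorm + np.log(np.abs(p)) - 0.5 * self.z * r
        return sign, log

    def grad_log(self, x):
        xb, r = self._r(x)
        p = 2.0 - self.z * r
        dlog_dr = -self.z / p - 0.5 * self.z
        return dlog_dr[:, None, None] * xb / r[:, None, None]

    def lap_log(self, x):
        _, r = self._r(x)
        p = 2.0 - self.z * r
        dlog = -self.z / p - 0.5 * self.z
        d2log = -self.z**2 / p**2
        return d2log + 2.0 * dlog / r


class Hydrogenic2pz(WaveFunction):
    """psi = (Z^5/(32 pi))^(1/2) z exp(-Z r / 2); E = -Z^2/8, odd in z."""

    n_particles, d = 1, 3

    def __init__(self, z: float = 1.0):
        self.z = float(z)
        self.energy = -self.z**2 / 8.0
        self._lognorm = 0.5 * math.log(self.z**5 / (32.0 * math.pi))

    def _r(self, x):
        xb, _ = batchify(x, 1, 3)
        return xb, np.linalg.norm(xb[:, 0, :], axis=-1)

    def sign_log(self, x):
        xb, r = self._r(x)
        zc = xb[:, 0, 2]
        with np.errstate(divide="ignore"):
            log = self._lognorm + np.log(np.abs(zc)) - 0.5 * self.z * r
        return np.sign(zc), log

    def grad_log(self, x):
        xb, r = self._r(x)
        zc = xb[:, 0, 2]
        g = -0.5 * self.z * xb / r[:, None, None]
        g[:, 0, 2] += 1.0 / zc
        return g

    def lap_log(self, x):
        xb, r = self._r(x)
        zc = xb[:, 0, 2]
        return -1.0 / zc**2 - self.z / r


class HarmonicEigenstate(WaveFunction):
    """k-th 1D harmonic-oscillator eigenstate, unit mass, frequency omega.

    psi_k(x) = N_k H_k(sqrt(omega) x) exp(-omega x^2 / 2), E = (k + 1/2) omega.
    """

    n_particles, d = 1, 1

    def __init__(self, k: int = 0, omega: float = 1.0):
        self.k = int(k)
        self.omega = float(omega)
        self.energy = (self.k + 0.5) * self.omega
        self._c = np.zeros(self.k + 1)
        self._c[self.k] = 1.0
        self._lognorm = 0.25 * math.log(self.omega / math.pi) - 0.5 * (
            self.k * math.log(2.0) + math.lgamma(self.k + 1)
        )

    def _parts(self, x):
        xb, _ = batchify(x, 1, 1)
        u = math.sqrt(self.omega) * xb[:, 0, 0]
        p = hermval(u, self._c)
        dp = hermval(u, hermder(self._c)) if self.k >= 1 else np.zeros_like(u)
        d2p = hermval(u, hermder(self._c, 2)) if self.k >= 2 else np.zeros_like(u)
        return xb, u, p, dp, d2p

    def sign_log(self, x):
        xb, u, p, _, _ = self._parts(x)
        with np.errstate(divide="ignore"):
            log = self._lognorm + np.log(np.abs(p)) - 0.5 * u**2
        return np.sign(p), log

    def grad_log(self, x):
        xb, u, p, dp, _ = self._parts(x)
        s = math.sqrt(self.omega)
        g = s * (dp / p - u)
        return g[:, None, None]

    def lap_log(self, x):
        xb, u, p, dp, d2p = self._parts(x)
        return self.omega * (d2p / p - (dp / p) ** 2 - 1.0)


class BoxEigenstate(WaveFunction):
    """k-th eigenstate of the infinite box on (0, L): sin(k pi x / L)."""

    n_particles, d = 1, 1

    def __init__(self, k: int = 1, length: float = 1.0):
        self.k = int(k)
        self.length = float(length)
        self.energy = (self.k * math.pi / self.length) ** 2 / 2.0

    def sign_log(self, x):
        xb, _ = batchify(x, 1, 1)
        u = xb[:, 0, 0]
        inside = (u > 0) & (u < self.length)
        s = np.sin(self.k * math.pi * u / self.length)
        with np.errstate(divide="ignore"):
            log = np.where(inside, np.log(np.abs(s) + 1e-300), -np.inf)
        return np.where(inside, np.sign(s), 0.0), log

    def grad_log(self, x):
        xb, _ = batchify(x, 1, 1)
        u = xb[:, 0, 0]
        w = self.k * math.pi / self.length
        return (w / np.tan(w * u))[:, None, None]

    def lap_log(self, x):
        xb, _ = batchify(x, 1, 1)
        u = xb[:, 0, 0]
        w = self.k * math.pi / self.length
        return -((w / np.sin(w * u)) ** 2)


class ExpSlater(WaveFunction):
    """One-electron 3D ansatz psi = exp(-alpha r), trainable alpha.

    Variational energy on hydrogen: E(alpha) = alpha^2/2 - alpha.
    """

    n_particles, d = 1, 3

    def __init__(self, alpha: float = 1.0):
        self.alpha = float(alpha)

    def get_params(self):
        return np.array([self.alpha])

    def set_params(self, vec):
        self.alpha = float(np.asarray(vec).ravel()[0])

    def param_groups(self):
        return {"orbitals": slice(0, 1)}

    def _r(self, x):
        xb, _ = batchify(x, 1, 3)
        return xb, np.linalg.norm(xb[:, 0, :], axis=-1)

    def sign_log(self, x):
        xb, r = self._r(x)
        return np.ones(xb.shape[0]), -self.alpha * r

    def grad_log(self, x):
        xb, r = self._r(x)
        return -self.alpha * xb / r[:, None, None]

    def lap_log(self, x):
        _, r = self._r(x)
        return -2.0 * self.alpha / r

    def param_grad_log(self, x):
        _, r = self._r(x)
        return -r[:, None]


class PolyGaussian1D(WaveFunction):
    """Flexible 1D ansatz psi = P(x) exp(-e^t x^2 / 2).

    P is a linear combination (trainable coefficients ``a``) of *normalized*
    Hermite functions N_k H_k(sqrt(s0) x) at a fixed feature scale s0 (the
    normalization keeps the coefficient directions comparably scaled, so
    plain gradient descent is well conditioned), and the envelope width e^t
    is trainable through its logarithm t, keeping it positive.  Spans
    polynomial-times-Gaussian states of arbitrary width; the exact harmonic
    eigenstates are the points a = one-hot, e^t = omega (with s0 = omega).
    """

    n_particles, d = 1, 1

    def __init__(self, coeffs, log_width: float = 0.0, feature_scale: float = 1.0,
                 train_width: bool = True):
        self.a = np.asarray(coeffs, dtype=float).copy()
        self.t = float(log_width)
        self.s0 = float(feature_scale)
        self.train_width = bool(train_width)
        k = np.arange(self.a.size)
        self._norms = (self.s0 / math.pi) ** 0.25 / np.sqrt(
            2.0**k * np.array([math.factorial(int(i)) for i in k])
        )

    # parameters: [a_0..a_K, t]
    def get_params(self):
        return np.concatenate([self.a, [self.t]])

    def set_params(self, vec):
        vec = np.asarray(vec, dtype=float).ravel()
        self.a = vec[:-1].copy()
        self.t = float(vec[-1])

    def param_groups(self):
        k = self.a.size
        return {"orbitals": slice(0, k), "envelope_width": slice(k, k + 1)}

    def trainable_mask(self):
        m = np.ones(self.a.size + 1, dtype=bool)
        m[-1] = self.train_width
        return m

    def _parts(self, x):
        xb, _ = batchify(x, 1, 1)
        u = math.sqrt(self.s0) * xb[:, 0, 0]
        c = self.a * self._norms
        p = hermval(u, c)
        dp = hermval(u, hermder(c)) if c.size > 1 else np.zeros_like(u)
        d2p = hermval(u, hermder(c, 2)) if c.size > 2 else np.zeros_like(u)
        return xb, u, p, dp, d2p

    def sign_log(self, x):
        xb, u, p, _, _ = self._parts(x)
        w = math.exp(self.t)
        with np.errstate(divide="ignore"):
            log = np.log(np.abs(p)) - 0.5 * w * xb[:, 0, 0] ** 2
        return np.sign(p), log

    def grad_log(self, x):
        xb, u, p, dp, _ = self._parts(x)
        w = math.exp(self.t)
        g = math.sqrt(self.s0) * dp / p - w * xb[:, 0, 0]
        return g[:, None, None]

    def lap_log(self, x):
        xb, u, p, dp, d2p = self._parts(x)
        w = math.exp(self.t)
        return self.s0 * (d2p / p - (dp / p) ** 2) - w

    def param_grad_log(self, x):
        xb, u, p, dp, d2p = self._parts(x)
        w = math.exp(self.t)
        out = np.zeros((xb.shape[0], self.a.size + 1))
        for k in range(self.a.size):
            c = np.zeros(k + 1)
            c[k] = self._norms[k]
            out[:, k] = hermval(u, c) / p
        out[:, -1] = -0.5 * w * xb[:, 0, 0] ** 2
        return out


class LinearCombination(WaveFunction):
    """psi = sum_k a_k psi_k over fixed component wavefunctions.

    Coefficients are the (optionally trainable) parameters; components must
    all share particle count and dimensionality.  Values and derivatives are
    combined at the psi level using stabilized relative weights, so the
    result is valid arbitrarily far into the tails.
    """

    def __init__(self, components, coeffs, trainable: bool = True):
        if len(components) != len(np.atleast_1d(coeffs)):
            raise ValueError("one coefficient per component")
        self.components = list(components)
        self.coeffs = np.asarray(coeffs, dtype=float).copy()
        self.trainable = bool(trainable)
        self.n_particles = components[0].n_particles
        self.d = components[0].d
        for c in components:
            if (c.n_particles, c.d) != (self.n_particles, self.d):
                raise ValueError("components must share shape")

    def get_params(self):
        return self.coeffs.copy()

    def set_params(self, vec):
        self.coeffs = np.asarray(vec, dtype=float).ravel().copy()

    def param_groups(self):
        return {"mixture": slice(0, self.coeffs.size)}

    def trainable_mask(self):
        return np.full(self.coeffs.size, self.trainable)

    def _weights(self, x):
        """Relative signed weights w_k = a_k s_k exp(l_k - m), and m."""
        xb, _ = batchify(x, self.n_particles, self.d)
        signs, logs = [], []
        for c in self.components:
            s, l = c.sign_log(xb)
            signs.append(s)
            logs.append(l)
        signs = np.stack(signs, axis=-1)  # (B, K)
        logs = np.stack(logs, axis=-1)
        m = np.max(np.where(np.isfinite(logs), logs, -np.inf), axis=-1)
        m = np.where(np.isfinite(m), m, 0.0)
        w = self.coeffs[None, :] * signs * np.exp(logs - m[:, None])
        return xb, w, m

    def sign_log(self, x):
        xb, w, m = self._weights(x)
        tot = np.sum(w, axis=-1)
        with np.errstate(divide="ignore"):
            log = m + np.log(np.abs(tot))
        return np.sign(tot), log

    def grad_log(self, x):
        xb, w, _ = self._weights(x)
        tot = np.sum(w, axis=-1)
        g = np.zeros_like(xb)
        for k, c in enumerate(self.components):
            g += (w[:, k] / tot)[:, None, None] * c.grad_log(xb)
        return g

    def lap_log(self, x):
        xb, w, _ = self._weights(x)
        tot = np.sum(w, axis=-1)
        lap_psi_over_psi = np.zeros(xb.shape[0])
        for k, c in enumerate(self.components):
            gk = c.grad_log(xb)
            lk = c.lap_log(xb)
            lap_psi_over_psi += (w[:, k] / tot) * (lk + np.sum(gk**2, axis=(1, 2)))
        g = self.grad_log(xb)
        return lap_psi_over_psi - np.sum(g**2, axis=(1, 2))

    def param_grad_log(self, x):
        # d ln|psi| / d a_k = psi_k / psi, computed with the shared offset m
        xb, w, m = self._weights(x)
        tot = np.sum(w, axis=-1)
        out = np.zeros((xb.shape[0], self.coeffs.size))
        for k, c in enumerate(self.components):
            s, l = c.sign_log(xb)
            out[:, k] = s * np.exp(l - m) / tot
        return out


class NormalizationWrapper(WaveFunction):
    """Multiplies a wavefunction by exp(c) with trainable c.

    A pure-normalization parameter: every norm-free estimator must have
    exactly zero gradient with respect to it.
    """

    def __init__(self, inner: WaveFunction, c: float = 0.0):
        self.inner = inner
        self.c = float(c)
        self.n_particles = inner.n_particles
        self.d = inner.d

    def get_params(self):
        return np.concatenate([self.inner.get_params(), [self.c]])

    def set_params(self, vec):
        vec = np.asarray(vec, dtype=float).ravel()
        self.inner.set_params(vec[:-1])
        self.c = float(vec[-1])

    def trainable_mask(self):
        return np.concatenate([self.inner.trainable_mask(), [True]])

    def param_groups(self):
        groups = dict(self.inner.param_groups())
        n = self.inner.n_params
        groups["norm"] = slice(n, n + 1)
        return groups

    def sign_log(self, x):
        s, l = self.inner.sign_log(x)
        return s, l + self.c

    def grad_log(self, x):
        return self.inner.grad_log(x)

    def lap_log(self, x):
        return self.inner.lap_log(x)

    def param_grad_log(self, x):
        inner = self.inner.param_grad_log(x)
        ones = np.ones((inner.shape[0], 1))
        return np.concatenate([inner, ones], axis=1)
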