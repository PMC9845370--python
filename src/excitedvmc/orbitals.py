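"""Single-electron basis functions with exact derivatives.

Each primitive maps points ``(M, 3)`` to values ``(M,)`` and supplies the
gradient ``(M, 3)`` and the *per-axis* second derivatives ``(M, 3)`` (the
diagonal of the Hessian), which is what the determinant machinery needs to
assemble Laplacians of backflow-dressed orbital matrices.

Slater-type primitives carry the nuclear cusp themselves; Gaussian
primitives are smooth and rely on the multiplicative cusp envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlaterS",
    "SlaterP",
    "GaussianS",
    "GaussianP",
    "gaussian_overlap",
]


def _radial_parts(pts: np.ndarray, center: np.ndarray):
    dx = pts - center[None, :]
    r = np.linalg.norm(dx, axis=-1)
    return dx, r


@dataclass(frozen=True)
class SlaterS:
    """r^(n-1) exp(-zeta r), an s-type Slater orbital (unnormalized)."""

    zeta: float
    n: int = 1
    center: tuple = (0.0, 0.0, 0.0)

    def _f(self, r):
        p = self.n - 1
        f = r**p * np.exp(-self.zeta * r)
        df = (p / r - self.zeta) * f
        d2f = (p * (p - 1) / r**2 - 2 * p * self.zeta / r + self.zeta**2) * f
        return f, df, d2f

    def value(self, pts):
        _, r = _radial_parts(pts, np.asarray(self.center))
        return self._f(r)[0]

    def grad(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        _, df, _ = self._f(r)
        return df[:, None] * dx / r[:, None]

    def hess_diag(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        _, df, d2f = self._f(r)
        u2 = (dx / r[:, None]) ** 2
        return d2f[:, None] * u2 + df[:, None] * (1.0 - u2) / r[:, None]


@dataclass(frozen=True)
class SlaterP:
    """x_axis * exp(-zeta r), a p-type Slater orbital (unnormalized)."""

    zeta: float
    axis: int = 2
    center: tuple = (0.0, 0.0, 0.0)

    def value(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        return dx[:, self.axis] * np.exp(-self.zeta * r)

    def grad(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        f = np.exp(-self.zeta * r)
        u = dx / r[:, None]
        g = dx[:, self.axis][:, None] * (-self.zeta * u) * f[:, None]
        g[:, self.axis] += f
        return g

    def hess_diag(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        f = np.exp(-self.zeta * r)
        u = dx / r[:, None]
        # d2/da2 [ z * f(r) ] = z * f_aa + 2 delta_{a,axis} f_a
        f_a = -self.zeta * u * f[:, None]
        f_aa = (self.zeta**2 * u**2 - self.zeta * (1.0 - u**2) / r[:, None]) * f[:, None]
        out = dx[:, self.axis][:, None] * f_aa
        out[:, self.axis] += 2.0 * f_a[:, self.axis]
        return out


@dataclass(frozen=True)
class GaussianS:
    """exp(-alpha |r - c|^2), s-type Cartesian Gaussian (unnormalized)."""

    alpha: float
    center: tuple = (0.0, 0.0, 0.0)

    def value(self, pts):
        dx, r = _radial_parts(pts, np.asarray(self.center))
        return np.exp(-self.alpha * r**2)

    def grad(self, pts):
        dx, _ = _radial_parts(pts, np.asarray(self.center))
        return -2.0 * self.alpha * dx * self.value(pts)[:, None]

    def hess_diag(self, pts):
        dx, _ = _radial_parts(pts, np.asarray(self.center))
        v = self.value(pts)[:, None]
        return (-2.0 * self.alpha + 4.0 * self.alpha**2 * dx**2) * v


@dataclass(frozen=True)
class GaussianP:
    """(x_axis - c_axis) exp(-alpha |r - c|^2), p-type Cartesian Gaussian."""

    alpha: float
    axis: int = 2
    center: tuple = (0.0, 0.0, 0.0)

    def value(self, pts):
        dx, _ = _radial_parts(pts, np.asarray(self.center))
        return dx[:, self.axis] * np.exp(-self.alpha * np.sum(dx**2, axis=-1))

    def grad(self, pts):
        dx, _ = _radial_parts(pts, np.asarray(self.center))
        e = np.exp(-self.alpha * np.sum(dx**2, axis=-1))[:, None]
        g = dx[:, self.axis][:, None] * (-2.0 * self.alpha * dx) * e
        g[:, self.axis] += e[:, 0]
        return g

    def hess_diag(self, pts):
        dx, _ = _radial_parts(pts, np.asarray(self.center))
        e = np.exp(-self.alpha * np.sum(dx**2, axis=-1))[:, None]
        e_a = -2.0 * self.alpha * dx * e
        e_aa = (-2.0 * self.alpha + 4.0 * self.alpha**2 * dx**2) * e
        out = dx[:, self.axis][:, None] * e_aa
        out[:, self.axis] += 2.0 * e_a[:, self.axis]
        return out


def gaussian_overlap(a, b) -> float:
    """Analytic overlap of two s/p Cartesian Gaussian primitives.

    Used to verify orthonormality of imported molecular orbitals without a
    3D quadrature grid.  Standard Gaussian-product-theorem closed forms.
    """
    import math

    A = np.asarray(a.center, dtype=float)
    B = np.asarray(b.center, dtype=float)
    al, be = a.alpha, b.alpha
    p = al + be
    mu = al * be / p
    ab2 = float(np.sum((A - B) ** 2))
    s00 = (math.pi / p) ** 1.5 * math.exp(-mu * ab2)
    P = (al * A + be * B) / p

    def kind(prim):
        return 0 if isinstance(prim, GaussianS) else 1

    ka, kb = kind(a), kind(b)
    if ka == 0 and kb == 0:
        return s00
    if ka == 1 and kb == 0:
        return (P[a.axis] - A[a.axis]) * s00
    if ka == 0 and kb == 1:
        return (P[b.axis] - B[b.axis]) * s00
    # p-p
    pa = P[a.axis] - A[a.axis]
    pb = P[b.axis] - B[b.axis]
    s = pa * pb * s00
    if a.axis == b.axis:
        s += s00 / (2.0 * p)
    return s
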