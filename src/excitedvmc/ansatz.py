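"""Trainable Slater-Jastrow-backflow trial wavefunctions.

The wavefunction is

    psi(r) = exp(gamma(r) + J(r)) * sum_p c_p det[phi~_up] det[phi~_down]

with a fixed cusp envelope gamma, a symmetric Jastrow factor J, and
generalized orbitals dressed by a permutation-equivariant backflow,

    phi~_{mu i}(r) = phi_mu(r_i) * f^m_{mu i}(r) + f^a_{mu i}(r).

Jastrow and backflow are built from sums of small scalar networks over
electron-electron and electron-nucleus distances, which keeps every
coordinate derivative (including per-axis second derivatives of the
determinant matrices) in closed form.  The determinant sum is evaluated as
a signed log-sum-exp; ln|det| derivatives use the standard trace identities

    d ln|det A| = tr(A^-1 dA),
    d2 ln|det A| = tr(A^-1 d2A) - tr((A^-1 dA)^2).

All distances enter the trainable networks through the smooth feature
s(r) = r^2 / (1 + r), whose derivative vanishes at coalescence, so the
trainable parts cannot disturb the cusp conditions carried by the envelope
(or by Slater-type orbitals).
"""

from __future__ import annotations

import numpy as np

from .network import ScalarMLP
from .wavefunction import WaveFunction, batchify

__all__ = ["CuspEnvelope", "Jastrow", "Backflow", "SlaterJastrowAnsatz"]

_EE_CUSP_OPPOSITE = 0.5
_EE_CUSP_SAME = 0.25


def _feature(r):
    """s(r) = r^2/(1+r): s(0)=0, s'(0)=0, s ~ r at large r."""
    s = r * r / (1.0 + r)
    s1 = (r * r + 2.0 * r) / (1.0 + r) ** 2
    s2 = 2.0 / (1.0 + r) ** 3
    return s, s1, s2


def _pair_geometry(x):
    """Distances and unit vectors between electrons; diagonal masked."""
    diff = x[:, :, None, :] - x[:, None, :, :]  # (B, N, N, d)
    r = np.linalg.norm(diff, axis=-1)
    n = x.shape[1]
    eye = np.eye(n, dtype=bool)
    r_safe = np.where(eye[None], 1.0, r)
    u = diff / r_safe[..., None]
    return r, r_safe, u, eye


def _en_geometry(x, nuclei):
    diff = x[:, :, None, :] - nuclei[None, None, :, :]  # (B, N, M, d)
    r = np.linalg.norm(diff, axis=-1)
    u = diff / r[..., None]
    return r, u


class CuspEnvelope:
    """Fixed (non-trainable) log-domain cusp envelope.

    gamma(r) = - sum_{i,I} Z_I q(r_iI) + sum_{i<j} c_ij q(r_ij),

    with q(r) = r/(1 + a r).  The radial slope of q at 0 is 1, so ln|psi|
    acquires slope -Z_I toward each nucleus (Kato condition) and slope 1/2
    (opposite spin) or 1/4 (same spin) at electron coalescences.  The
    range parameter a (``range_scale``) controls how quickly the envelope
    saturates: q -> 1/a within ~1/a bohr, beyond which the factor is
    constant and therefore does not disturb the orthogonality of the
    baseline orbitals it multiplies.  The same-spin term is isolated
    behind a switch so it can be disabled.
    """

    def __init__(self, charges=None, positions=None, spins=None,
                 nuclear=True, electronic=True, same_spin=True,
                 range_scale=2.0):
        self.charges = None if charges is None else np.asarray(charges, dtype=float)
        self.positions = None if positions is None else np.asarray(positions, dtype=float)
        self.spins = None if spins is None else np.asarray(spins, dtype=float)
        self.nuclear = nuclear and self.charges is not None
        self.electronic = electronic
        self.same_spin = same_spin
        self.range_scale = float(range_scale)

    def _pair_slopes(self, n):
        if self.spins is None:
            same = np.zeros((n, n), dtype=bool)
        else:
            same = self.spins[:, None] == self.spins[None, :]
        c = np.where(same, _EE_CUSP_SAME if self.same_spin else 0.0, _EE_CUSP_OPPOSITE)
        return c

    def evaluate(self, x, d: int = 3):
        """Return (value (B,), grad (B,N,d), lap (B,))."""
        B, n = x.shape[0], x.shape[1]
        val = np.zeros(B)
        grad = np.zeros_like(x)
        lap = np.zeros(B)
        a = self.range_scale
        if self.nuclear:
            r, u = _en_geometry(x, self.positions)
            q = r / (1.0 + a * r)
            q1 = 1.0 / (1.0 + a * r) ** 2
            q2 = -2.0 * a / (1.0 + a * r) ** 3
            z = self.charges[None, None, :]
            val -= np.sum(z * q, axis=(1, 2))
            grad -= np.sum(z[..., None] * q1[..., None] * u, axis=2)
            lap -= np.sum(z * (q2 + (d - 1) * q1 / r), axis=(1, 2))
        if self.electronic and n > 1:
            r, r_safe, u, eye = _pair_geometry(x)
            c = self._pair_slopes(n)[None]
            q = r_safe / (1.0 + a * r_safe)
            q1 = 1.0 / (1.0 + a * r_safe) ** 2
            q2 = -2.0 * a / (1.0 + a * r_safe) ** 3
            mask = ~eye[None]
            val += 0.5 * np.sum(np.where(mask, c * q, 0.0), axis=(1, 2))
            grad += np.sum(np.where(mask[..., None], (c * q1)[..., None] * u, 0.0), axis=2)
            lap += 0.5 * np.sum(
                np.where(mask, 2.0 * c * (q2 + (d - 1) * q1 / r_safe), 0.0), axis=(1, 2)
            )
        return val, grad, lap

    def __call__(self, x):
        """gamma(r) only, shape (B,)."""
        return self.evaluate(np.asarray(x, dtype=float))[0]


class Jastrow:
    """Symmetric correlation factor from scalar networks over distances.

    J(r) = sum_{i<j} u_{s(ij)}(s(r_ij)) + sum_{i,I} w(s(r_iI)),

    with separate networks for same- and opposite-spin pairs.  Symmetric
    under like-spin exchange by construction, hence it cannot move nodes.
    """

    def __init__(self, spins, n_nuclei=0, hidden=(32, 32), seed=0):
        self.spins = np.asarray(spins, dtype=float)
        n = self.spins.size
        same = self.spins[:, None] == self.spins[None, :]
        self.has_same = bool(np.any(same[np.triu_indices(n, 1)])) if n > 1 else False
        self.has_opp = bool(np.any(~same[np.triu_indices(n, 1)])) if n > 1 else False
        self.n_nuclei = n_nuclei
        self.u_same = ScalarMLP(hidden, seed=seed * 7 + 1) if self.has_same else None
        self.u_opp = ScalarMLP(hidden, seed=seed * 7 + 2) if self.has_opp else None
        self.w_en = ScalarMLP(hidden, seed=seed * 7 + 3) if n_nuclei > 0 else None

    @property
    def nets(self):
        return [n for n in (self.u_same, self.u_opp, self.w_en) if n is not None]

    @property
    def n_params(self):
        return sum(n.n_params for n in self.nets)

    def get_params(self):
        if not self.nets:
            return np.zeros(0)
        return np.concatenate([n.theta for n in self.nets])

    def set_params(self, vec):
        off = 0
        for n in self.nets:
            n.theta = np.asarray(vec[off: off + n.n_params], dtype=float).copy()
            off += n.n_params

    def evaluate(self, x, nuclei=None, d=3):
        """(value (B,), grad (B,N,d), lap (B,))."""
        B, n = x.shape[0], x.shape[1]
        val = np.zeros(B)
        grad = np.zeros_like(x)
        lap = np.zeros(B)
        if n > 1 and (self.has_same or self.has_opp):
            r, r_safe, u, eye = _pair_geometry(x)
            same = (self.spins[:, None] == self.spins[None, :])[None]
            s, s1, s2 = _feature(r_safe)
            f = np.zeros_like(r)
            f1 = np.zeros_like(r)
            f2 = np.zeros_like(r)
            for net, sel in ((self.u_same, same), (self.u_opp, ~same)):
                if net is None:
                    continue
                v, dv, d2v = net.value_d1_d2(s)
                f = np.where(sel, v, f)
                f1 = np.where(sel, dv * s1, f1)
                f2 = np.where(sel, d2v * s1**2 + dv * s2, f2)
            mask = ~eye[None]
            val += 0.5 * np.sum(np.where(mask, f, 0.0), axis=(1, 2))
            grad += np.sum(np.where(mask[..., None], f1[..., None] * u, 0.0), axis=2)
            lap += np.sum(np.where(mask, f2 + (d - 1) * f1 / r_safe, 0.0), axis=(1, 2))
        if self.w_en is not None and nuclei is not None:
            r, u = _en_geometry(x, nuclei)
            s, s1, s2 = _feature(r)
            v, dv, d2v = self.w_en.value_d1_d2(s)
            val += np.sum(v, axis=(1, 2))
            grad += np.sum((dv * s1)[..., None] * u, axis=2)
            lap += np.sum(d2v * s1**2 + dv * s2 + (d - 1) * dv * s1 / r, axis=(1, 2))
        return val, grad, lap

    def param_grad(self, x, nuclei=None):
        """d J / d theta, (B, P)."""
        B, n = x.shape[0], x.shape[1]
        outs = []
        r_ee = None
        if n > 1:
            r_ee, r_safe, _, eye = _pair_geometry(x)
            same = (self.spins[:, None] == self.spins[None, :])[None] & ~eye[None]
            opp = (self.spins[:, None] != self.spins[None, :])[None]
            s_ee = _feature(r_safe)[0]
        for net, sel in (
            (self.u_same, "same"), (self.u_opp, "opp"), (self.w_en, "en")
        ):
            if net is None:
                continue
            if sel == "en":
                r, _ = _en_geometry(x, nuclei)
                s = _feature(r)[0]
                g = net.param_grad(s)  # (B, N, M, P)
                outs.append(np.sum(g, axis=(1, 2)))
            else:
                mask = same if sel == "same" else opp
                g = net.param_grad(s_ee)  # (B, N, N, P)
                outs.append(0.5 * np.sum(np.where(mask[..., None], g, 0.0), axis=(1, 2)))
        if not outs:
            return np.zeros((B, 0))
        return np.concatenate(outs, axis=-1)


class Backflow:
    """Permutation-equivariant dressing of the orbital matrix.

    A scalar invariant feature per electron,

        g_i(r) = sum_{j != i} chi(s(r_ij)) + sum_I xi(s(r_iI)),

    feeds per-orbital linear heads producing the multiplicative and
    additive components f^m_{mu i} = 1 + a^m_mu g_i and f^a_{mu i} =
    a^a_mu g_i.  Heads are initialized to zero, so the untrained ansatz is
    exactly the Slater-Jastrow baseline (identity backflow).
    """

    def __init__(self, n_orbitals, n_particles, n_nuclei=0, hidden=(32, 32), seed=0):
        self.n_orbitals = n_orbitals
        self.chi = ScalarMLP(hidden, seed=seed * 7 + 4, zero_output=False) if n_particles > 1 else None
        self.xi = ScalarMLP(hidden, seed=seed * 7 + 5, zero_output=False) if n_nuclei > 0 else None
        self.am = np.zeros(n_orbitals)
        self.aa = np.zeros(n_orbitals)

    @property
    def nets(self):
        return [n for n in (self.chi, self.xi) if n is not None]

    @property
    def n_params(self):
        return 2 * self.n_orbitals + sum(n.n_params for n in self.nets)

    def get_params(self):
        parts = [self.am, self.aa] + [n.theta for n in self.nets]
        return np.concatenate(parts)

    def set_params(self, vec):
        k = self.n_orbitals
        self.am = np.asarray(vec[:k], dtype=float).copy()
        self.aa = np.asarray(vec[k: 2 * k], dtype=float).copy()
        off = 2 * k
        for n in self.nets:
            n.theta = np.asarray(vec[off: off + n.n_params], dtype=float).copy()
            off += n.n_params

    def features(self, x, nuclei=None, d=3):
        """g (B,N), dg (B,N,N,d) with dg[b,i,k,a] = dg_i/dx_{k,a},
        d2g (B,N,N,d) the per-axis diagonal second derivatives, and the
        parameter gradient dg/dtheta_net (B,N,Pnets)."""
        B, n = x.shape[0], x.shape[1]
        g = np.zeros((B, n))
        dg = np.zeros((B, n, n, x.shape[2]))
        d2g = np.zeros_like(dg)
        pgrads = []
        if self.chi is not None and n > 1:
            r, r_safe, u, eye = _pair_geometry(x)
            mask = ~eye[None]
            s, s1, s2 = _feature(r_safe)
            v, dv, d2v = self.chi.value_d1_d2(s)
            f1 = dv * s1
            f2 = d2v * s1**2 + dv * s2
            g += np.sum(np.where(mask, v, 0.0), axis=2)
            # dg_i/dx_i
            own = np.sum(np.where(mask[..., None], f1[..., None] * u, 0.0), axis=2)
            for a in range(x.shape[2]):
                dg[:, :, :, a][:, np.arange(n), np.arange(n)] += own[:, :, a]
            # dg_i/dx_k (k != i): -f1(r_ik) u_ik
            cross = np.where(mask[..., None], -f1[..., None] * u, 0.0)
            dg += cross
            radial2 = f2 * u.transpose(3, 0, 1, 2) ** 2 + f1 * (
                1.0 - u.transpose(3, 0, 1, 2) ** 2
            ) / r_safe
            radial2 = radial2.transpose(1, 2, 3, 0)  # (B,N,N,d)
            own2 = np.sum(np.where(mask[..., None], radial2, 0.0), axis=2)
            for a in range(x.shape[2]):
                d2g[:, :, :, a][:, np.arange(n), np.arange(n)] += own2[:, :, a]
            d2g += np.where(mask[..., None], radial2, 0.0)
            pg = self.chi.param_grad(s)  # (B,N,N,P)
            pgrads.append(np.sum(np.where(mask[..., None], pg, 0.0), axis=2))
        if self.xi is not None and nuclei is not None:
            r, u = _en_geometry(x, nuclei)
            s, s1, s2 = _feature(r)
            v, dv, d2v = self.xi.value_d1_d2(s)
            f1 = dv * s1
            f2 = d2v * s1**2 + dv * s2
            g += np.sum(v, axis=2)
            own = np.sum(f1[..., None] * u, axis=2)
            own2 = np.sum(
                f2[..., None] * u**2 + (f1 / r)[..., None] * (1.0 - u**2), axis=2
            )
            for a in range(x.shape[2]):
                dg[:, :, :, a][:, np.arange(n), np.arange(n)] += own[:, :, a]
                d2g[:, :, :, a][:, np.arange(n), np.arange(n)] += own2[:, :, a]
            pgrads.append(np.sum(self.xi.param_grad(s), axis=2))
        pg = np.concatenate(pgrads, axis=-1) if pgrads else np.zeros((B, n, 0))
        return g, dg, d2g, pg


class SlaterJastrowAnsatz(WaveFunction):
    """Multi-determinant Slater-Jastrow(-backflow) trial state for a molecule.

    Parameters
    ----------
    system : MolecularSystem
    primitives : list of basis functions (value/grad/hess_diag contract).
    orbital_coeffs : (K_orb, K_prim) matrix c_{mu k}; orbitals are
        phi_mu = sum_k c_{mu k} phi_k.
    determinants : list of (up_occupation, down_occupation) orbital-index
        tuples; lengths must equal n_up and n_down.
    det_coeffs : expansion coefficients c_p.
    use_jastrow, use_backflow : include the trainable factors.
    envelope : a :class:`CuspEnvelope` or None.  Slater-type bases carry
        their own nuclear cusp; pass an envelope with ``nuclear=False`` then.
    train_* : per-group trainable flags ("fixed-spin mode" freezes c_p).
    """

    n_particles, d = None, 3

    def __init__(self, system, primitives, orbital_coeffs, determinants,
                 det_coeffs, use_jastrow=True, use_backflow=False,
                 envelope=None, hidden=(32, 32), seed=0,
                 train_dets=True, train_orbitals=True, train_jastrow=True,
                 train_backflow=True):
        self.system = system
        self.n_particles = system.n_electrons
        self.primitives = list(primitives)
        self.C = np.atleast_2d(np.asarray(orbital_coeffs, dtype=float)).copy()
        self.dets = [(tuple(u), tuple(dn)) for u, dn in determinants]
        self.cp = np.atleast_1d(np.asarray(det_coeffs, dtype=float)).copy()
        if len(self.dets) != self.cp.size or len(self.dets) < 1:
            raise ValueError("need one coefficient per determinant, at least one")
        for u, dn in self.dets:
            if len(u) != system.n_up or len(dn) != system.n_down:
                raise ValueError(
                    f"occupation sizes {(len(u), len(dn))} do not match "
                    f"electron counts {(system.n_up, system.n_down)}"
                )
            if max(list(u) + list(dn) + [0]) >= self.C.shape[0]:
                raise ValueError("occupation index exceeds orbital count")
        if self.C.shape[0] < max(system.n_up, system.n_down):
            raise ValueError("need at least max(n_up, n_down) orbitals")
        self.envelope = envelope
        self.jastrow = (
            Jastrow(system.spins(), system.n_nuclei, hidden, seed)
            if use_jastrow else None
        )
        self.backflow = (
            Backflow(self.C.shape[0], self.n_particles, system.n_nuclei, hidden, seed)
            if use_backflow else None
        )
        self.train_flags = {
            "determinants": train_dets,
            "orbitals": train_orbitals,
            "jastrow": train_jastrow,
            "backflow": train_backflow,
        }

    # ---- parameter plumbing -------------------------------------------
    def param_groups(self):
        groups = {}
        off = 0
        groups["determinants"] = slice(off, off + self.cp.size)
        off += self.cp.size
        groups["orbitals"] = slice(off, off + self.C.size)
        off += self.C.size
        nj = self.jastrow.n_params if self.jastrow else 0
        groups["jastrow"] = slice(off, off + nj)
        off += nj
        nb = self.backflow.n_params if self.backflow else 0
        groups["backflow"] = slice(off, off + nb)
        return groups

    def get_params(self):
        parts = [self.cp, self.C.ravel()]
        if self.jastrow:
            parts.append(self.jastrow.get_params())
        if self.backflow:
            parts.append(self.backflow.get_params())
        return np.concatenate(parts)

    def set_params(self, vec):
        vec = np.asarray(vec, dtype=float).ravel()
        g = self.param_groups()
        self.cp = vec[g["determinants"]].copy()
        self.C = vec[g["orbitals"]].reshape(self.C.shape).copy()
        if self.jastrow:
            self.jastrow.set_params(vec[g["jastrow"]])
        if self.backflow:
            self.backflow.set_params(vec[g["backflow"]])

    def trainable_mask(self):
        m = np.zeros(self.n_params, dtype=bool)
        for name, sl in self.param_groups().items():
            m[sl] = self.train_flags[name]
        return m

    # ---- evaluation core ----------------------------------------------
    def _orbital_arrays(self, x, need_derivs):
        B, n, _ = x.shape
        kp = len(self.primitives)
        pts = x.reshape(-1, 3)
        pv = np.stack([p.value(pts) for p in self.primitives], axis=-1)
        pv = pv.reshape(B, n, kp)
        phi = np.einsum("bnk,mk->bnm", pv, self.C)
        if not need_derivs:
            return pv, phi, None, None
        pgd = np.stack([p.grad(pts) for p in self.primitives], axis=-2)
        phd = np.stack([p.hess_diag(pts) for p in self.primitives], axis=-2)
        phig = np.einsum("bnka,mk->bnma", pgd.reshape(B, n, kp, 3), self.C)
        phih = np.einsum("bnka,mk->bnma", phd.reshape(B, n, kp, 3), self.C)
        return pv, phi, phig, phih

    def dressed_orbitals(self, x):
        """Backflow-dressed orbital matrices per spin channel.

        Returns (up, down) arrays of shape (B, n_spin, K_orb); equivariant
        under like-spin permutation of the input configuration.
        """
        xb, _ = batchify(x, self.n_particles, 3)
        _, phi, _, _ = self._orbital_arrays(xb, need_derivs=False)
        if self.backflow is not None:
            g, _, _, _ = self.backflow.features(xb, self.system.positions)
            fm = 1.0 + g[:, :, None] * self.backflow.am[None, None, :]
            fa = g[:, :, None] * self.backflow.aa[None, None, :]
            phi = phi * fm + fa
        nu = self.system.n_up
        return phi[:, :nu, :], phi[:, nu:, :]

    def _channels(self):
        nu, nd = self.system.n_up, self.system.n_down
        return ((0, nu), (nu, nu + nd))

    def _compute(self, x, need_derivs=False, need_param=False):
        B, n, _ = x.shape
        nuclei = self.system.positions
        pv, phi, phig, phih = self._orbital_arrays(x, need_derivs or need_param)

        if self.backflow is not None:
            g, dg, d2g, dg_dtheta = self.backflow.features(x, nuclei)
            am, aa = self.backflow.am, self.backflow.aa
            fm = 1.0 + g[:, :, None] * am[None, None, :]           # (B,N,K)
            fa = g[:, :, None] * aa[None, None, :]
            head = phi * am[None, None, :] + aa[None, None, :]      # d entry / d g_i
        else:
            g = dg = d2g = dg_dtheta = None
            fm = np.ones_like(phi)
            fa = np.zeros_like(phi)
            head = None

        phit = phi * fm + fa  # dressed orbital matrix (B, N, K)

        # ---- per-determinant quantities
        P = len(self.dets)
        signs = np.ones((B, P))
        logs = np.zeros((B, P))
        grads = np.zeros((B, P, n, 3)) if need_derivs else None
        laps = np.zeros((B, P)) if need_derivs else None
        dln_dC = np.zeros((B, P, *self.C.shape)) if need_param else None
        dln_dam = np.zeros((B, P, self.C.shape[0])) if need_param else None
        dln_daa = np.zeros((B, P, self.C.shape[0])) if need_param else None
        dln_dbfnet = (
            np.zeros((B, P, dg_dtheta.shape[-1]))
            if (need_param and self.backflow is not None) else None
        )

        for p, (occ_u, occ_d) in enumerate(self.dets):
            for (lo, hi), occ in zip(self._channels(), (occ_u, occ_d)):
                ns = hi - lo
                if ns == 0:
                    continue
                occ = np.asarray(occ, dtype=int)
                rows = np.arange(lo, hi)
                A = phit[:, rows][:, :, occ]  # (B, ns, ns)
                sgn, ld = np.linalg.slogdet(A)
                signs[:, p] *= sgn
                logs[:, p] += ld
                if not (need_derivs or need_param):
                    continue
                ok = sgn != 0
                Ainv = np.empty_like(A)
                Ainv[ok] = np.linalg.inv(A[ok])
                Ainv[~ok] = np.nan

                if need_derivs:
                    # dA[b, k, a, i, c]
                    dA = np.zeros((B, n, 3, ns, ns))
                    d2A = np.zeros_like(dA)
                    own_g = phig[:, rows][:, :, occ]     # (B,ns,K?,3)->(B,ns,ns,3)
                    own_h = phih[:, rows][:, :, occ]
                    fm_s = fm[:, rows][:, :, occ]
                    for i_loc, e in enumerate(rows):
                        dA[:, e, :, i_loc, :] += (own_g[:, i_loc] * fm_s[:, i_loc, :, None]).transpose(0, 2, 1)
                    if self.backflow is not None:
                        head_s = head[:, rows][:, :, occ]  # (B,ns,ns)
                        dg_s = dg[:, rows]                 # (B,ns,N,3)
                        d2g_s = d2g[:, rows]
                        dA += np.einsum("bic,bika->bkaic", head_s, dg_s)
                        d2A += np.einsum("bic,bika->bkaic", head_s, d2g_s)
                        am_s = am[occ]
                        for i_loc, e in enumerate(rows):
                            cross = 2.0 * own_g[:, i_loc] * am_s[None, :, None] \
                                * dg_s[:, i_loc, e, :][:, None, :]
                            d2A[:, e, :, i_loc, :] += cross.transpose(0, 2, 1)
                    for i_loc, e in enumerate(rows):
                        d2A[:, e, :, i_loc, :] += (own_h[:, i_loc] * fm_s[:, i_loc, :, None]).transpose(0, 2, 1)
                    t1 = np.einsum("bqi,bkaiq->bka", Ainv, dA)
                    grads[:, p] += t1
                    t2 = np.einsum("bqi,bkaiq->bka", Ainv, d2A)
                    M = np.einsum("bqi,bkaij->bkaqj", Ainv, dA)
                    t3 = np.einsum("bkaqj,bkajq->bka", M, M)
                    laps[:, p] += np.sum(t2 - t3, axis=(1, 2))

                if need_param:
                    pv_s = pv[:, rows]                    # (B,ns,Kp)
                    fm_s = fm[:, rows][:, :, occ]
                    # orbital coefficients: dA[i,c]/dC[mu,k] = [mu==occ_c] pv[i,k] fm[i,c]
                    contrib = np.einsum("bci,bik,bic->bck", Ainv, pv_s, fm_s)
                    for c_loc, mu in enumerate(occ):
                        dln_dC[:, p, mu, :] += contrib[:, c_loc, :]
                    if self.backflow is not None:
                        g_s = g[:, rows]
                        phi_s = phi[:, rows][:, :, occ]
                        base = np.einsum("bci,bic,bi->bc", Ainv, phi_s, g_s)
                        for c_loc, mu in enumerate(occ):
                            dln_dam[:, p, mu] += base[:, c_loc]
                        base_a = np.einsum("bci,bi->bc", Ainv, g_s)
                        for c_loc, mu in enumerate(occ):
                            dln_daa[:, p, mu] += base_a[:, c_loc]
                        head_s = head[:, rows][:, :, occ]
                        K_e = np.einsum("bci,bic->bi", Ainv, head_s)  # (B,ns)
                        dln_dbfnet[:, p] += np.einsum(
                            "bi,bit->bt", K_e, dg_dtheta[:, rows]
                        )

        # ---- combine determinants (signed log-sum-exp)
        with np.errstate(invalid="ignore"):
            m = np.max(np.where(np.isfinite(logs), logs, -np.inf), axis=1)
        m = np.where(np.isfinite(m), m, 0.0)
        w = self.cp[None, :] * signs * np.exp(logs - m[:, None])  # (B,P)
        tot = np.sum(w, axis=1)
        sign_det = np.sign(tot)
        with np.errstate(divide="ignore"):
            log_det = m + np.log(np.abs(tot))

        out = {"sign": sign_det, "log": log_det}
        rel = w / np.where(tot == 0.0, np.nan, tot)[:, None]

        if need_derivs:
            Gdet = np.einsum("bp,bpna->bna", rel, grads)
            lap_ratio = np.einsum(
                "bp,bp->b", rel, laps + np.sum(grads**2, axis=(2, 3))
            )
            out["grad_det"] = Gdet
            out["lap_det"] = lap_ratio - np.sum(Gdet**2, axis=(1, 2))
        if need_param:
            out["dln_dcp"] = signs * np.exp(logs - m[:, None]) / tot[:, None]
            out["dln_dC"] = np.einsum("bp,bpmk->bmk", rel, dln_dC)
            if self.backflow is not None:
                out["dln_dam"] = np.einsum("bp,bpm->bm", rel, dln_dam)
                out["dln_daa"] = np.einsum("bp,bpm->bm", rel, dln_daa)
                out["dln_dbfnet"] = np.einsum("bp,bpt->bt", rel, dln_dbfnet)
        return out

    def _additive(self, x, need_derivs):
        B, n = x.shape[0], x.shape[1]
        val = np.zeros(B)
        grad = np.zeros_like(x)
        lap = np.zeros(B)
        if self.envelope is not None:
            v, g, l = self.envelope.evaluate(x)
            val, grad, lap = val + v, grad + g, lap + l
        if self.jastrow is not None:
            v, g, l = self.jastrow.evaluate(x, self.system.positions)
            val, grad, lap = val + v, grad + g, lap + l
        return val, grad, lap

    # ---- WaveFunction interface ---------------------------------------
    def sign_log(self, x):
        xb, _ = batchify(x, self.n_particles, 3)
        core = self._compute(xb)
        add = self._additive(xb, False)[0]
        return core["sign"], core["log"] + add

    def grad_log(self, x):
        xb, _ = batchify(x, self.n_particles, 3)
        core = self._compute(xb, need_derivs=True)
        return core["grad_det"] + self._additive(xb, True)[1]

    def lap_log(self, x):
        xb, _ = batchify(x, self.n_particles, 3)
        core = self._compute(xb, need_derivs=True)
        return core["lap_det"] + self._additive(xb, True)[2]

    def grad_and_lap_log(self, x):
        xb, _ = batchify(x, self.n_particles, 3)
        core = self._compute(xb, need_derivs=True)
        _, g, l = self._additive(xb, True)
        return core["grad_det"] + g, core["lap_det"] + l

    def param_grad_log(self, x):
        xb, _ = batchify(x, self.n_particles, 3)
        core = self._compute(xb, need_param=True)
        B = xb.shape[0]
        parts = [core["dln_dcp"], core["dln_dC"].reshape(B, -1)]
        if self.jastrow is not None:
            parts.append(self.jastrow.param_grad(xb, self.system.positions))
        if self.backflow is not None:
            parts.append(core["dln_dam"])
            parts.append(core["dln_daa"])
            parts.append(core["dln_dbfnet"])
        return np.concatenate(parts, axis=1)
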