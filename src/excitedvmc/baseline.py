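"""Baseline (initial) states for the joint optimization.

For solvable systems the baseline is analytic: hydrogenic Slater orbitals
or harmonic-oscillator eigenfunctions, one (multi-)determinant per state,
mutually orthogonal by construction.  For molecules the baseline is an
imported set of products from an external multi-configuration engine
(molecular-orbital coefficients over a Gaussian basis, CI determinant
lists, active-space metadata), truncated to a determinant budget by
largest |coefficient|.  The import is engine-agnostic: any program that
can emit the JSON payload documented in :func:`import_casscf` works.

Gaussian baseline orbitals have no nuclear cusp; the fixed multiplicative
envelope supplies it, leaving the baseline nodal structure intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ansatz import CuspEnvelope, SlaterJastrowAnsatz
from .orbitals import GaussianP, GaussianS, SlaterP, SlaterS, gaussian_overlap
from .states import HarmonicEigenstate, PolyGaussian1D
from .systems import HarmonicPotential, MolecularSystem, ModelSystem

__all__ = ["BaselineSolution", "analytic_baseline", "import_casscf",
           "export_payload", "select_determinants", "build_states"]

ORTHONORMAL_TOL = 1e-6


@dataclass
class BaselineSolution:
    """Initial orbitals plus per-state determinant expansions."""

    primitives: list                 # shared basis functions
    mo_coeff: np.ndarray             # (n_orbitals, n_primitives)
    determinants: list               # per state: list of (up_occ, down_occ)
    coefficients: list               # per state: np.ndarray of c_p
    n_states: int
    active_space: dict = field(default_factory=dict)
    multiplicities: Optional[list] = None
    kind: str = "analytic"

    def __post_init__(self):
        for c in self.coefficients:
            if len(c) < 1:
                raise ValueError("each state needs at least one determinant")


def select_determinants(coefficients, max_dets: int):
    """Keep the max_dets determinants of largest |c_p| per state.

    Retained coefficients are renormalized to unit norm; order is stable:
    descending |c_p| with ties broken by original index.  Returns
    (kept index lists, renormalized coefficient arrays).
    """
    if max_dets < 1:
        raise ValueError("max_dets must be >= 1")
    kept_idx, kept_c = [], []
    for c in coefficients:
        c = np.asarray(c, dtype=float)
        order = np.argsort(-np.abs(c), kind="stable")[:max_dets]
        cc = c[order]
        kept_idx.append(order.tolist())
        kept_c.append(cc / np.linalg.norm(cc))
    return kept_idx, kept_c


def analytic_baseline(system, n_states: int) -> BaselineSolution:
    """Closed-form baseline for solvable systems.

    Hydrogenic atoms get the exact 1s/2s/2p_z Slater-orbital ladder;
    1D harmonic traps get Hermite-function states.  States are mutually
    orthogonal by construction.
    """
    if isinstance(system, MolecularSystem):
        if system.n_nuclei != 1 or system.n_electrons != 1:
            raise ValueError("analytic molecular baselines cover hydrogenic atoms")
        z = float(system.charges[0])
        center = tuple(system.positions[0])
        if n_states > 3:
            raise ValueError("hydrogenic analytic baseline provides 3 orbitals")
        prims = [
            SlaterS(z, 1, center),            # e^{-Zr}
            SlaterS(z / 2.0, 1, center),      # e^{-Zr/2}
            SlaterS(z / 2.0, 2, center),      # r e^{-Zr/2}
            SlaterP(z / 2.0, 2, center),      # z e^{-Zr/2}
        ]
        mo = np.array([
            [1.0, 0.0, 0.0, 0.0],             # 1s
            [0.0, 2.0, -z, 0.0],              # 2s  (2 - Zr) e^{-Zr/2}
            [0.0, 0.0, 0.0, 1.0],             # 2p_z
        ])[:max(n_states, 1)]
        dets = [[((k,), ())] for k in range(n_states)]
        coeffs = [np.array([1.0]) for _ in range(n_states)]
        return BaselineSolution(prims, mo, dets, coeffs, n_states,
                                active_space={"electrons": 1,
                                              "orbitals": n_states},
                                multiplicities=[2] * n_states)
    if isinstance(system, ModelSystem) and isinstance(system.potential, HarmonicPotential) \
            and system.d == 1 and system.n_particles == 1:
        omega = system.potential.omega
        dets = [[((k,), ())] for k in range(n_states)]
        coeffs = [np.array([1.0]) for _ in range(n_states)]
        mo = np.eye(n_states)
        return BaselineSolution([HarmonicEigenstate(k, omega) for k in range(n_states)],
                                mo, dets, coeffs, n_states, kind="harmonic")
    raise ValueError("no analytic baseline for this system")


def build_states(baseline: BaselineSolution, system, n_states=None,
                 flexible=True, n_poly=6, width_mismatch=1.0,
                 use_jastrow=True, use_backflow=False, hidden=(16, 16),
                 seed=0, fixed_spin=False):
    """Construct one trainable trial state per baseline state.

    Harmonic baselines become flexible polynomial-times-Gaussian ansatzes
    (``width_mismatch`` scales the initial envelope width away from the
    exact one to make the optimization non-trivial); molecular baselines
    become Slater-Jastrow(-backflow) ansatzes sharing the baseline basis.
    ``fixed_spin`` freezes the determinant coefficients, keeping each
    state in the spin sector of its baseline.
    """
    n_states = n_states or baseline.n_states
    if baseline.kind == "harmonic":
        omega = baseline.primitives[0].omega
        states = []
        for k in range(n_states):
            a = np.zeros(max(n_poly, n_states))
            a[k] = 1.0
            states.append(PolyGaussian1D(
                a, log_width=float(np.log(omega * width_mismatch)),
                feature_scale=omega, train_width=flexible))
        return states
    states = []
    slater_basis = any(isinstance(p, (SlaterS, SlaterP)) for p in baseline.primitives)
    envelope = None
    if not slater_basis:
        envelope = CuspEnvelope(system.charges, system.positions, system.spins())
    for k in range(n_states):
        idx, cc = select_determinants([baseline.coefficients[k]], max_dets=10)
        dets = [baseline.determinants[k][i] for i in idx[0]]
        states.append(SlaterJastrowAnsatz(
            system, baseline.primitives, baseline.mo_coeff.copy(), dets, cc[0],
            use_jastrow=use_jastrow, use_backflow=use_backflow,
            envelope=envelope, hidden=hidden, seed=seed + k,
            train_dets=not fixed_spin,
        ))
    return states


# ---------------------------------------------------------------------------
# engine-agnostic import/export


_PRIM_TAGS = {
    "gaussian_s": (GaussianS, ("alpha", "center")),
    "gaussian_p": (GaussianP, ("alpha", "axis", "center")),
    "slater_s": (SlaterS, ("zeta", "n", "center")),
    "slater_p": (SlaterP, ("zeta", "axis", "center")),
}


def _prim_to_dict(p):
    for tag, (cls, fields) in _PRIM_TAGS.items():
        if type(p) is cls:
            return {"type": tag, **{f: getattr(p, f) for f in fields}}
    raise ValueError(f"unsupported primitive {type(p)}")


def _prim_from_dict(d):
    cls, fields = _PRIM_TAGS[d["type"]]
    kwargs = {f: d[f] for f in fields}
    if "center" in kwargs:
        kwargs["center"] = tuple(kwargs["center"])
    return cls(**kwargs)


def export_payload(baseline: BaselineSolution) -> dict:
    """Serialize a baseline to a JSON-compatible payload (bit-exact)."""
    return {
        "basis": [_prim_to_dict(p) for p in baseline.primitives],
        "mo_coeff": baseline.mo_coeff.tolist(),
        "states": [
            {
                "determinants": [
                    {"up": list(u), "down": list(dn)} for u, dn in dets
                ],
                "coefficients": list(map(float, c)),
            }
            for dets, c in zip(baseline.determinants, baseline.coefficients)
        ],
        "active_space": baseline.active_space,
        "multiplicities": baseline.multiplicities,
    }


def import_casscf(payload, n_states: int,
                  check_orthonormal: bool = True) -> BaselineSolution:
    """Build a baseline from external multi-configuration products.

    ``payload`` is a dict (or JSON string) with keys

    - ``basis``: list of primitive descriptors ({"type": "gaussian_s",
      "alpha": ..., "center": [x,y,z]}, p-type adds "axis"),
    - ``mo_coeff``: molecular-orbital coefficient matrix (orbitals x
      primitives),
    - ``states``: per state a determinant list ({"up": [...], "down":
      [...]}) and coefficients,
    - optional ``active_space`` and ``multiplicities`` metadata.

    Gaussian orbitals are checked for orthonormality with analytic
    overlap integrals (tolerance 1e-6); missing CI vectors for the
    requested number of states raise a configuration error.
    """
    if isinstance(payload, str):
        payload = json.loads(payload)
    prims = [_prim_from_dict(d) for d in payload["basis"]]
    mo = np.asarray(payload["mo_coeff"], dtype=float)
    states = payload["states"]
    if len(states) < n_states:
        raise ValueError(
            f"payload provides {len(states)} states, {n_states} requested"
        )
    if check_orthonormal and all(
        isinstance(p, (GaussianS, GaussianP)) for p in prims
    ):
        s = np.array([[gaussian_overlap(a, b) for b in prims] for a in prims])
        gram = mo @ s @ mo.T
        if np.max(np.abs(gram - np.eye(len(mo)))) > ORTHONORMAL_TOL:
            raise ValueError(
                "imported molecular orbitals are not orthonormal "
                f"(max deviation {np.max(np.abs(gram - np.eye(len(mo)))):.2e})"
            )
    dets, coeffs = [], []
    for st in states[:n_states]:
        d = [(tuple(x["up"]), tuple(x["down"])) for x in st["determinants"]]
        c = np.asarray(st["coefficients"], dtype=float)
        if len(d) != c.size or c.size == 0:
            raise ValueError("determinant list and coefficients mismatch")
        dets.append(d)
        coeffs.append(c / np.linalg.norm(c))
    return BaselineSolution(
        prims, mo, dets, coeffs, n_states,
        active_space=payload.get("active_space", {}),
        multiplicities=payload.get("multiplicities"),
        kind="imported",
    )
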