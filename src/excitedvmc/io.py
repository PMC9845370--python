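"""Geometry input, checkpoints and results output.

XYZ files follow the conventional layout (atom count, comment, element +
three coordinates per line).  Coordinates default to angstrom per the XYZ
convention; a "bohr" or "angstrom" tag in the comment line, or an explicit
``units`` argument, overrides that.  Atomic units are used internally
(1 angstrom = 1.8897259886 bohr).

Checkpoints are NumPy archives with named parameter groups per state plus
a JSON sidecar carrying hyperparameters, seeds and the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .systems import ANGSTROM_TO_BOHR, MolecularSystem

__all__ = ["load_xyz", "load_geometry", "save_checkpoint", "load_checkpoint",
           "config_hash", "ELEMENTS"]

ELEMENTS = {
    s: z + 1 for z, s in enumerate(
        "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn "
        "Fe Co Ni Cu Zn Ga Ge As Se Br Kr".split()
    )
}


def load_xyz(path, units=None):
    """Read an XYZ file; returns (charges, positions_bohr).

    ``units`` may be "bohr" or "angstrom"; if None, a unit tag in the
    comment line is honored and angstrom is assumed otherwise.
    """
    lines = Path(path).read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: not a valid XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must contain the atom count")
    comment = lines[1].lower()
    if units is None:
        if "bohr" in comment or "a.u." in comment or "au" in comment.split():
            units = "bohr"
        elif "angstrom" in comment:
            units = "angstrom"
        else:
            units = "angstrom"
    if units not in ("bohr", "angstrom"):
        raise ValueError(f"unknown units {units!r}")
    body = lines[2: 2 + n]
    if len(body) < n:
        raise ValueError(f"{path}: expected {n} atom lines, found {len(body)}")
    charges, positions = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENTS:
            raise ValueError(f"{path}: unknown element symbol {parts[0]!r}")
        charges.append(ELEMENTS[sym])
        positions.append([float(v) for v in parts[1:4]])
    positions = np.asarray(positions, dtype=float)
    if units == "angstrom":
        positions = positions * ANGSTROM_TO_BOHR
    return np.asarray(charges), positions


def load_geometry(path, charge: int = 0, multiplicity: int = 1,
                  units=None) -> MolecularSystem:
    """XYZ file -> MolecularSystem with validated electron counts.

    N = sum(Z) - charge and N_up - N_down = multiplicity - 1 must yield
    non-negative integer spin-channel counts.
    """
    charges, positions = load_xyz(path, units)
    n = int(np.sum(charges)) - charge
    if n < 1:
        raise ValueError(f"charge {charge} leaves {n} electrons")
    excess = multiplicity - 1
    if excess < 0 or (n - excess) % 2 != 0 or n - excess < 0:
        raise ValueError(
            f"multiplicity {multiplicity} inconsistent with {n} electrons"
        )
    n_down = (n - excess) // 2
    n_up = n - n_down
    return MolecularSystem(charges, positions, n_up, n_down)


def config_hash(config_dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path, states, iteration: int, meta=None):
    """Parameter vectors per state in an .npz container + JSON sidecar."""
    path = Path(path)
    arrays = {f"state_{i}": s.get_params() for i, s in enumerate(states)}
    np.savez(path, iteration=np.array(iteration), **arrays)
    sidecar = {
        "iteration": iteration,
        "n_states": len(states),
        "groups": [
            {name: [sl.start, sl.stop] for name, sl in s.param_groups().items()}
            for s in states
        ],
    }
    if meta:
        sidecar.update(meta)
    with open(str(path) + ".json", "w") as f:
        json.dump(sidecar, f, indent=1)


def load_checkpoint(path, states):
    """Restore parameters (bit-exact) into existing state objects."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    data = np.load(path)
    for i, s in enumerate(states):
        s.set_params(data[f"state_{i}"])
    return int(data["iteration"])
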