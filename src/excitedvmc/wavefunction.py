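"""The trial-wavefunction contract.

Every wavefunction exposes its value in sign/log form together with *exact*
first and second coordinate derivatives of ln|psi| and the parameter
gradient of ln|psi|.  All derivative formulas are closed-form (chain rule
through the analytic building blocks), never finite differences; the
finite-difference route exists only as a test oracle.

Configurations are arrays of shape ``(B, N, d)`` (a single ``(N, d)``
configuration is promoted).  Signs are in {-1, 0, +1}; a sign of 0 marks a
node, where ln|psi| is reported as -inf.
"""

from __future__ import annotations

import numpy as np

__all__ = ["WaveFunction", "batchify"]


def batchify(x: np.ndarray, n: int, d: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return x[None], True
    if x.ndim != 3 or x.shape[1:] != (n, d):
        raise ValueError(f"expected configurations of shape (B, {n}, {d}), got {x.shape}")
    return x, False


class WaveFunction:
    """Base class; subclasses fill in n_particles, d and the evaluations."""

    n_particles: int = 1
    d: int = 1

    # ---- parameter interface -------------------------------------------
    @property
    def n_params(self) -> int:
        return self.get_params().size

    def get_params(self) -> np.ndarray:
        """Flat copy of all parameters (trainable and frozen)."""
        return np.zeros(0)

    def set_params(self, vec: np.ndarray) -> None:
        if np.asarray(vec).size != 0:
            raise ValueError("this wavefunction has no parameters")

    def trainable_mask(self) -> np.ndarray:
        """Boolean mask over the flat parameter vector; frozen entries False."""
        return np.ones(self.n_params, dtype=bool)

    def param_groups(self) -> dict:
        """Mapping group name -> slice into the flat parameter vector."""
        return {}

    # ---- evaluations ----------------------------------------------------
    def sign_log(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def grad_log(self, x: np.ndarray) -> np.ndarray:
        """d ln|psi| / d r, shape (B, N, d)."""
        raise NotImplementedError

    def lap_log(self, x: np.ndarray) -> np.ndarray:
        """sum_i lap_i ln|psi|, shape (B,)."""
        raise NotImplementedError

    def param_grad_log(self, x: np.ndarray) -> np.ndarray:
        """d ln|psi| / d theta for every parameter, shape (B, P)."""
        if self.n_params == 0:
            xb, _ = batchify(x, self.n_particles, self.d)
            return np.zeros((xb.shape[0], 0))
        raise NotImplementedError

    # ---- conveniences ---------------------------------------------------
    def log_abs(self, x: np.ndarray) -> np.ndarray:
        return self.sign_log(x)[1]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """psi itself (may under/overflow; prefer sign_log)."""
        s, l = self.sign_log(x)
        return s * np.exp(l)
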