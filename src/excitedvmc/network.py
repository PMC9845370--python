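"""Small dense networks over scalar distance features.

The Jastrow factor and backflow are built from permutation-invariant sums of
scalar functions of interparticle distances, each represented by a small
tanh multilayer perceptron R -> R.  Because the input is a single scalar,
exact first and second derivatives with respect to the input propagate
through the layers in closed form (second-order forward mode), and the
parameter gradient is ordinary backpropagation.  No numerical differencing
anywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ScalarMLP"]


class ScalarMLP:
    """Tanh MLP with scalar input and scalar output.

    Parameters are held in a flat vector.  The final layer is linear and is
    initialized to zero so the network output (and all its derivatives)
    vanish at step 0 -- fresh Jastrow/backflow components leave the baseline
    wavefunction untouched.
    """

    def __init__(self, hidden: tuple[int, ...] = (32, 32), seed: int = 0,
                 init_scale: float = 1.0, zero_output: bool = True):
        rng = np.random.default_rng(seed)
        dims = [1, *hidden, 1]
        self.shapes = []
        params = []
        for k in range(len(dims) - 1):
            fan_in, fan_out = dims[k], dims[k + 1]
            w = rng.normal(0.0, init_scale / np.sqrt(fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            if zero_output and k == len(dims) - 2:
                w = np.zeros_like(w)
            self.shapes.append((fan_in, fan_out))
            params.extend([w.ravel(), b])
        self.theta = np.concatenate(params)

    # ---- parameter plumbing -------------------------------------------
    @property
    def n_params(self) -> int:
        return self.theta.size

    def _unpack(self, theta=None):
        theta = self.theta if theta is None else theta
        out, off = [], 0
        for fan_in, fan_out in self.shapes:
            w = theta[off: off + fan_in * fan_out].reshape(fan_in, fan_out)
            off += fan_in * fan_out
            b = theta[off: off + fan_out]
            off += fan_out
            out.append((w, b))
        return out

    # ---- evaluation ----------------------------------------------------
    def value(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=float)[..., None]
        layers = self._unpack()
        for k, (w, b) in enumerate(layers):
            a = a @ w + b
            if k < len(layers) - 1:
                a = np.tanh(a)
        return a[..., 0]

    def value_d1_d2(self, x: np.ndarray):
        """(f, f', f'') with respect to the scalar input, any input shape."""
        a = np.asarray(x, dtype=float)[..., None]
        d1 = np.ones_like(a)
        d2 = np.zeros_like(a)
        layers = self._unpack()
        for k, (w, b) in enumerate(layers):
            a = a @ w + b
            d1 = d1 @ w
            d2 = d2 @ w
            if k < len(layers) - 1:
                t = np.tanh(a)
                sech2 = 1.0 - t**2
                d2 = sech2 * d2 - 2.0 * t * sech2 * d1**2
                d1 = sech2 * d1
                a = t
        return a[..., 0], d1[..., 0], d2[..., 0]

    def param_grad(self, x: np.ndarray) -> np.ndarray:
        """d f(x) / d theta, shape x.shape + (n_params,)."""
        a = np.asarray(x, dtype=float)[..., None]
        layers = self._unpack()
        acts = [a]
        pre = []
        for k, (w, b) in enumerate(layers):
            z = acts[-1] @ w + b
            pre.append(z)
            acts.append(np.tanh(z) if k < len(layers) - 1 else z)
        # reverse pass: delta = d out / d z_k
        grads = [None] * len(layers)
        delta = np.ones_like(pre[-1])
        for k in range(len(layers) - 1, -1, -1):
            w, _ = layers[k]
            gw = acts[k][..., :, None] * delta[..., None, :]
            grads[k] = (gw, delta)
            if k > 0:
                delta = (delta @ w.T) * (1.0 - np.tanh(pre[k - 1]) ** 2)
        flat = []
        for gw, gb in grads:
            flat.append(gw.reshape(*gw.shape[:-2], -1))
            flat.append(gb)
        return np.concatenate(flat, axis=-1)
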