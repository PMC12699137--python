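"""Minimal feedforward network with reverse-mode gradients.

The policy approximator is tiny (4 hidden layers of 20 leaky-rectifier
units), so the forward pass and exact backpropagation are written
directly in numpy.  ``backward`` accepts per-sample gradients of a
scalar loss with respect to the network outputs and returns gradients
with respect to all weights and biases, which is all the score-function
policy-gradient estimator needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    """Fully connected network with leaky-ReLU hidden layers and linear output.

    Parameters are held as a flat list alternating weight matrices and
    bias vectors, initialized with fan-in-scaled (He) Gaussians.
    """

    def __init__(
        self,
        layer_sizes: list[int],
        rng: np.random.Generator,
        negative_slope: float = 0.01,
    ) -> None:
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output layer")
        self.layer_sizes = list(layer_sizes)
        self.negative_slope = float(negative_slope)
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.params.append(w)
            self.params.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes) - 1

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Evaluate the network on a batch (n, d_in) -> (n, d_out).

        If ``cache`` is a list it is filled with the layer inputs needed
        by :meth:`backward`.
        """
        x = np.asarray(x, dtype=float)
        h = x
        for layer in range(self.n_layers):
            if cache is not None:
                cache.append(h)
            w, b = self.params[2 * layer], self.params[2 * layer + 1]
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise FloatingPointError("non-finite network weights")
            z = h @ w + b
            h = z if layer == self.n_layers - 1 else np.where(z > 0, z, self.negative_slope * z)
        return h

    def backward(self, cache: list, d_out: np.ndarray) -> list[np.ndarray]:
        """Backpropagate per-sample output gradients ``d_out`` (n, d_out).

        Returns gradients in the same layout as :attr:`params`, summed
        over the batch.
        """
        grads: list[np.ndarray] = [None] * len(self.params)
        delta = np.asarray(d_out, dtype=float)
        for layer in range(self.n_layers - 1, -1, -1):
            h = cache[layer]
            w = self.params[2 * layer]
            grads[2 * layer] = h.T @ delta
            grads[2 * layer + 1] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ w.T
                # activation derivative at the *input* of this layer, which is
                # the output of the previous layer's leaky ReLU
                delta = np.where(h > 0, delta, self.negative_slope * delta)
        return grads

    # -- serialization ------------------------------------------------------

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        i = 0
        for p in self.params:
            p[...] = flat[i : i + p.size].reshape(p.shape)
            i += p.size
        if i != flat.size:
            raise ValueError("flat parameter vector has wrong length")

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)
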