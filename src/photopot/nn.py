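"""Minimal feed-forward network engine (numpy) used by the atomic subnetworks.

Implements exactly what the potential needs and nothing more: a smooth
(tanh) multilayer perceptron with a linear scalar output, analytic
backpropagation for both parameter gradients and input gradients (the
latter feed the force evaluation), and an Adam optimizer. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected tanh network with linear output, one scalar per input row."""

    def __init__(self, layer_sizes: tuple[int, ...], rng: np.random.Generator):
        if len(layer_sizes) < 2 or layer_sizes[-1] != 1:
            raise ValueError("need at least (in, ..., 1) layer sizes ending in 1")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))  # Glorot
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [np.array(p, dtype=float) for p in params[:k]]
        self.biases = [np.array(p, dtype=float) for p in params[k:]]

    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.layer_sizes = self.layer_sizes
        clone.weights = [w.copy() for w in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        return clone

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Row-wise scalar outputs, shape (n,). With ``cache`` also return activations."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        activations = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + b)
            activations.append(h)
        out = (h @ self.weights[-1] + self.biases[-1])[:, 0]
        if cache:
            return out, activations
        return out

    def backward(self, activations: list[np.ndarray], dout: np.ndarray):
        """Backpropagate per-row output gradients ``dout`` (shape (n,)).

        Returns ``(param_grads, input_grad)`` where param_grads aligns with
        :meth:`parameters` and input_grad has the shape of the input batch.
        """
        delta = np.atleast_2d(np.asarray(dout, dtype=float)).T  # (n, 1)
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = activations[layer]
            grads_w[layer] = a_prev.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            delta = delta @ self.weights[layer].T
            if layer > 0:
                delta = delta * (1.0 - activations[layer] ** 2)  # tanh'
        return grads_w + grads_b, delta

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d output_row / d input_row for each row, shape like X."""
        _, acts = self.forward(X, cache=True)
        _, din = self.backward(acts, np.ones(acts[0].shape[0]))
        return din


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray],
             lr: float | None = None) -> None:
        self.t += 1
        lr = self.lr if lr is None else lr
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
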