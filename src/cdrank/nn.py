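"""Minimal feed-forward network stack (numpy): MLP layers, Adam, training loop.

Shared by the Siamese encoders, the reconstruction autoencoder and the dense
end classifier. Fully deterministic under a seed: one ``numpy`` Generator
drives weight initialization and dropout masks; training is plain
single-threaded dense algebra.
"""

from __future__ import annotations

import numpy as np

def _sigmoid_act(z):
    return sigmoid(z)


_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
    "sigmoid": (lambda z: _sigmoid_act(z), lambda z, a: a * (1.0 - a)),
}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class MLP:
    """Fully connected network with a configurable output activation.

    ``dims = [in, h1, ..., out]``; hidden layers use ``activation`` followed by
    inverted dropout during training; the output layer applies
    ``final_activation`` (default linear). He-uniform initialization.
    """

    def __init__(self, dims, activation: str = "relu", dropout: float = 0.0,
                 final_activation: str = "linear",
                 rng: np.random.Generator | None = None):
        if len(dims) < 2 or any(d <= 0 for d in dims):
            raise ValueError("dims must list >= 2 positive layer sizes")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for act in (activation, final_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        rng = rng or np.random.default_rng()
        self.dims = list(dims)
        self.activation = activation
        self.final_activation = final_activation
        self.dropout = dropout
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def input_dim(self) -> int:
        return self.dims[0]

    @property
    def output_dim(self) -> int:
        return self.dims[-1]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (output, cache); cache feeds :meth:`backward`."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"input has width {x.shape[1]}, expected {self.input_dim}")
        act, _ = _ACTIVATIONS[self.activation]
        final_act, _ = _ACTIVATIONS[self.final_activation]
        cache = {"inputs": [x], "zs": [], "masks": []}
        h = x
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            cache["zs"].append(z)
            if i < n_layers - 1:
                h = act(z)
                if training and self.dropout > 0.0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = final_act(z)
            cache["inputs"].append(h)
        return h, cache

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of a scalar loss wrt parameters and the network input,
        given dL/d(output). Returns (grads_W, grads_b, grad_input)."""
        act, dact = _ACTIVATIONS[self.activation]
        final_act, final_dact = _ACTIVATIONS[self.final_activation]
        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        z_last = cache["zs"][-1]
        delta = np.asarray(grad_out, dtype=float) * final_dact(z_last, final_act(z_last))
        for i in reversed(range(len(self.weights))):
            h_in = cache["inputs"][i]
            grads_W[i] = h_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            delta = delta @ self.weights[i].T
            if i > 0:
                mask = cache["masks"][i - 1]
                if mask is not None:
                    delta = delta * mask
                z_prev = cache["zs"][i - 1]
                delta = delta * dact(z_prev, act(z_prev))
        return grads_W, grads_b, delta

    # -- parameter bookkeeping -------------------------------------------------
    def parameters(self):
        return self.weights + self.biases

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s


class Adam:
    """Adaptive-moment gradient optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class EarlyStopper:
    """Tracks the best validation loss; signals a stop after ``patience`` bad epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_state = None
        self.bad_epochs = 0

    def update(self, loss: float, state) -> bool:
        """Record an epoch; returns True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_state = [p.copy() for p in state]
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience
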