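"""Minimal numpy neural-network kernels for the temporal gesture model.

Implements exactly the pieces the recurrent discrete-gesture classifier
needs — stacked LSTM layers, dense layers, per-sample instance normalization,
ReLU, softmax cross-entropy, Adam and a step learning-rate schedule — with
hand-derived backward passes.  Gradient correctness is pinned down by
finite-difference tests rather than an autodiff framework.

Shapes: sequence inputs are (batch, time, features); the LSTM returns the
hidden state at every step so the caller can gather the state at each
sequence's true final step (zero-padding beyond it never influences that
state).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LSTMLayer",
    "Dense",
    "InstanceNorm",
    "Relu",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "StepLR",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer:
    """One LSTM layer; gate order (input, forget, cell, output).

    Single weight matrix over the concatenated [x, h] input; forget-gate bias
    initialized to 1 (standard recipe for gradient flow early in training).
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(input_dim + hidden)
        self.params = {
            "W": rng.uniform(-scale, scale, (input_dim + hidden, 4 * hidden)),
            "b": np.zeros(4 * hidden),
        }
        self.params["b"][hidden : 2 * hidden] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.input_dim = input_dim
        self.hidden = hidden
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            zx = np.concatenate([xt, h], axis=1)
            z = zx @ W + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            cache.append((zx, i, f, g, o, c_prev, tc))
        self._cache = (x.shape, cache)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        (B, T, D), cache = self._cache
        H = self.hidden
        W = self.params["W"]
        dW = self.grads["W"]
        db = self.grads["b"]
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            zx, i, f, g, o, c_prev, tc = cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += zx.T @ dz
            db += dz.sum(axis=0)
            dzx = dz @ W.T
            dx[:, t, :] = dzx[:, :D]
            dh_next = dzx[:, D:]
            dc_next = dc * f
        return dx


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, (n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class InstanceNorm:
    """Per-sample normalization across the feature dimension (no affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self.params = {}
        self.grads = {}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (x - mu) * inv
        self._cache = (y, inv)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, inv = self._cache
        m1 = dy.mean(axis=1, keepdims=True)
        m2 = (dy * y).mean(axis=1, keepdims=True)
        return inv * (dy - m1 - y * m2)


class Relu:
    def __init__(self):
        self.params = {}
        self.grads = {}
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.
    """
    B = logits.shape[0]
    p = softmax(logits)
    loss = -float(np.mean(np.log(p[np.arange(B), targets] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(B), targets] -= 1.0
    return loss, dlogits / B


class Adam:
    """Adaptive-moment optimizer over a list of layers' parameter dicts."""

    def __init__(
        self,
        layers,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()}
            for l in self.layers
        ]

    def zero_grad(self) -> None:
        for l in self.layers:
            for g in l.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class StepLR:
    """lr = lr0 * gamma ** floor(epoch / step)."""

    def __init__(self, optimizer: Adam, step: int, gamma: float):
        self.opt = optimizer
        self.lr0 = optimizer.lr
        self.step_size = step
        self.gamma = gamma

    def at_epoch(self, epoch: int) -> float:
        """Set (and return) the learning rate for a 0-based epoch index."""
        lr = self.lr0 * self.gamma ** (epoch // self.step_size)
        self.opt.lr = lr
        return lr
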