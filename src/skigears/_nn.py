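"""Minimal NumPy neural-network engine: Conv1D / LSTM / Dense / Dropout
layers with backpropagation, softmax cross-entropy, and RMSprop.

Kept deliberately small — just the pieces the gear classifier needs.
Shapes follow the (batch, time, channels) convention throughout.  All
randomness (init, dropout, shuffling) flows through explicit Generators,
so a fixed seed reproduces training exactly.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over the time axis, stride 1, 'same' padding."""

    def __init__(self, n_in: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        self.n_in = n_in
        self.filters = filters
        self.W = _glorot(rng, (kernel * n_in, filters), kernel * n_in, filters)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k = self.kernel
        pad_l, pad_r = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        return np.concatenate([xp[:, i:i + T, :] for i in range(k)], axis=2)

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, dy):
        B, T, C = self._x_shape
        k = self.kernel
        flat_cols = self._cols.reshape(-1, k * C)
        flat_dy = dy.reshape(-1, self.filters)
        self.grads[0][...] = flat_cols.T @ flat_dy
        self.grads[1][...] = flat_dy.sum(axis=0)
        dcols = dy @ self.W.T  # (B, T, k*C)
        pad_l, pad_r = (k - 1) // 2, k // 2
        dxp = np.zeros((B, T + pad_l + pad_r, C))
        for i in range(k):
            dxp[:, i:i + T, :] += dcols[:, :, i * C:(i + 1) * C]
        return dxp[:, pad_l:pad_l + T, :]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training forward pass needs a Generator"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    """Affine map applied to the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads[0][...] = x2.T @ dy2
        self.grads[1][...] = dy2.sum(axis=0)
        return (dy @ self.W.T).reshape(self._x.shape)


class LSTM(Layer):
    """Single LSTM layer (gate order i, f, g, o; forget bias 1)."""

    def __init__(self, n_in: int, units: int, return_sequences: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        u = units
        self.W = _glorot(rng, (n_in, 4 * u), n_in, 4 * u)
        self.U = _glorot(rng, (u, 4 * u), u, 4 * u)
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train, rng):
        B, T, _ = x.shape
        u = self.units
        self._x = x
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        H = np.empty((B, T, u))
        for t in range(T):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h))
        self._H = H
        return H if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        u = self.units
        dW, dU, db = (np.zeros_like(self.W), np.zeros_like(self.U),
                      np.zeros_like(self.b))
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, _h = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, t, :]
            elif t == T - 1:
                dh += dy
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.concatenate([
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                dh * tc * o * (1.0 - o),
            ], axis=1)
            h_prev = self._H[:, t - 1, :] if t > 0 else np.zeros((B, u))
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        self.grads[0][...] = dW
        self.grads[1][...] = dU
        self.grads[2][...] = db
        return dx


class TakeLast(Layer):
    """Select the final time step (used when an LSTM returns sequences)."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float((onehot * np.log(p + eps)).sum() / n)
    return loss, (p - onehot) / n


class RMSprop:
    """Keras-default RMSprop: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 rho: float = 0.9, eps: float = 1e-7) -> None:
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache, strict=True):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
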