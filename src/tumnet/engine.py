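"""Minimal NumPy neural-network engine backing the Tumnet model.

Implements exactly the layer set the architecture needs — 3x3 "same"
convolution (via im2col and BLAS matmul), batch normalization, ReLU,
2x2/stride-2 max pooling, flatten, dropout, and a fully connected
layer — together with softmax cross-entropy loss and SGD with momentum.
Arrays are channels-last float32 batches of shape (B, H, W, C).

All randomness (weight init, dropout masks) flows through a single
``numpy.random.Generator`` so training is reproducible bit for bit from
one seed on a fixed BLAS configuration.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Forward/backward interface; parameters exposed for the optimizer."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Arrays that must survive save/load (weights, running stats)."""
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            getattr(self, key)[...] = value


def _im2col(x_padded: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """(B, H+2, W+2, C) -> (B*H*W, 9*C) patch matrix for a 3x3 window."""
    win = sliding_window_view(x_padded, (3, 3), axis=(1, 2))  # (B,H,W,C,3,3)
    b = win.shape[0]
    c = win.shape[3]
    col = win.transpose(0, 1, 2, 4, 5, 3)  # (B,H,W,3,3,C)
    return np.ascontiguousarray(col).reshape(b * out_h * out_w, 9 * c)


class Conv3x3Same(Layer):
    """3x3 convolution, stride 1, zero "same" padding, He-uniform init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (9 * c_in))
        self.w = rng.uniform(-limit, limit, size=(9 * c_in, c_out)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out
        self._col: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train):
        b, h, w, _ = x.shape
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        col = _im2col(xp, h, w)
        self._col = col if train else None
        out = col @ self.w + self.b
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout):
        b, h, w, _ = self._in_shape
        dflat = dout.reshape(-1, self.c_out)
        self.dw[...] = self._col.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcol = (dflat @ self.w.T).reshape(b, h, w, 3, 3, self.c_in)
        dxp = np.zeros((b, h + 2, w + 2, self.c_in), dtype=DTYPE)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
        self._col = None
        return dxp[:, 1:-1, 1:-1, :]

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state_arrays(self):
        return {"w": self.w, "b": self.b}


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx.astype(DTYPE, copy=False)

    def params_and_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_arrays(self):
        return {
            "gamma": self.gamma, "beta": self.beta,
            "running_mean": self.running_mean, "running_var": self.running_var,
        }


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0)
        self._mask = (x > 0) if train else None
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 window, stride 2; odd trailing rows/columns are dropped
    (floor geometry, so 227 -> 113)."""

    def forward(self, x, train):
        b, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * oh, : 2 * ow, :].reshape(b, oh, 2, ow, 2, c)
        out = xc.max(axis=(2, 4))
        if train:
            self._x_blocks = xc
            self._out = out
        return out

    def backward(self, dout):
        b, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        mask = self._x_blocks == self._out[:, :, None, :, None, :]
        # split gradient among ties (ties are rare with float activations)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        grad = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, : 2 * oh, : 2 * ow, :] = grad.reshape(b, 2 * oh, 2 * ow, c)
        self._x_blocks = self._out = None
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def state_arrays(self):
        return {"w": self.w, "b": self.b}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient wrt logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class SGDMomentum:
    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self._pairs = [pg for layer in layers for pg in layer.params_and_grads()]
        self._velocity = [np.zeros_like(p) for p, _ in self._pairs]

    def step(self) -> None:
        for v, (p, g) in zip(self._velocity, self._pairs):
            v *= self.momentum
            v -= self.lr * g
            p += v
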