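"""Minimal CPU neural-network engine (numpy, hand-written backprop).

Provides exactly the pieces the imaging stages need: 3x3 same-padding
convolutions, 2x2 max-pooling, nearest-neighbour upsampling, dense layers,
ReLU/sigmoid nonlinearities, Adam, and BCE/MSE losses.  Tensors are NCHW
float32/float64 numpy arrays; every layer caches what its backward pass needs.
All randomness (initialisation, batch order) comes from an explicit Generator,
so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "Flatten",
    "Reshape",
    "Adam",
    "mse_loss",
    "bce_with_logits",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix, same padding, stride 1."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Layer:
    def params(self):  # [(array, grad), ...]
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or any odd k) same-padding stride-1 convolution, He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, co, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.dw[...] = (dflat.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dflat.sum(axis=0)
        # dx: correlate dout with the flipped, in/out-swapped kernel
        w_rot = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
        cols_d = _im2col(dout, self.k)
        dx = cols_d @ w_rot.reshape(w_rot.shape[0], -1).T
        nn, cc, hh, ww = self._xshape
        return dx.reshape(n, h, w, cc).transpose(0, 3, 1, 2)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    """2x2 max pooling; input H, W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = [pg for lay in layers for pg in lay.params()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return float(loss), (p - target) / z.size
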