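"""Minimal numpy CNN machinery: layers, losses, SGD with momentum.

Everything uses channels-last layout ``(N, H, W, C)``.  Convolutions are
"valid" (no padding), stride 1, computed as a sum of k*k shifted matrix
products — fast under BLAS without an im2col buffer, and the identical
summation order in patchwise and dense application keeps the two numerically
interchangeable.  Max pooling is 2x2, stride 2, with floor truncation of odd
trailing rows/columns.

This module is deliberately framework-free; the architecture and training
conventions live in :mod:`histoscreen.model`.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

__all__ = ["Conv2D", "MaxPool2", "ReLU", "Flatten", "Dense", "SGDMomentum",
           "softmax", "softmax_cross_entropy"]


class Layer:
    """Base layer; subclasses implement forward/backward and expose params."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Valid convolution, stride 1, weights ``(k, k, C_in, C_out)``.

    Forward runs as one im2col GEMM; the input gradient reuses the k*k
    shifted-slice decomposition to avoid a col2im scatter.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng=None, dtype=np.float32):
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        if rng is None:
            self.W = np.zeros((kernel, kernel, in_ch, out_ch), dtype=dtype)
        else:
            scale = np.sqrt(2.0 / (kernel * kernel * in_ch))
            self.W = (scale * rng.standard_normal((kernel, kernel, in_ch, out_ch))).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (N, Ho, Wo, C, kh, kw) -> rows ordered (kh, kw, C) to match W
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return col.reshape(-1, k * k * self.in_ch)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        n, h, w, _ = x.shape
        ho, wo = h - k + 1, w - k + 1
        col = self._im2col(x)
        y = col @ self.W.reshape(-1, self.out_ch)
        y = y.reshape(n, ho, wo, self.out_ch)
        y += self.b
        if train:
            self._col = col
            self._x_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col = self._col
        assert col is not None, "backward before forward(train=True)"
        k = self.k
        n, ho, wo, _ = dy.shape
        dy2 = dy.reshape(-1, self.out_ch)
        self.dW[...] = (col.T @ dy2).reshape(self.W.shape)
        self.db[:] = dy2.sum(axis=0)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dx[:, di : di + ho, dj : dj + wo, :] += dy @ self.W[di, dj].T
        self._col = None
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped.

    Gradient routes to the first maximal element of each window in
    (top-left, top-right, bottom-left, bottom-right) order.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xe = x[:, : 2 * h2, : 2 * w2, :]
        quads = (
            xe[:, 0::2, 0::2, :],
            xe[:, 0::2, 1::2, :],
            xe[:, 1::2, 0::2, :],
            xe[:, 1::2, 1::2, :],
        )
        y = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        if train:
            self._in_shape = x.shape
            self._quads = quads
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        rem = dy
        slices = ((0, 0), (0, 1), (1, 0), (1, 1))
        for quad, (oi, oj) in zip(self._quads, slices):
            hit = quad == self._y
            dx[:, oi : 2 * h2 : 2, oj : 2 * w2 : 2, :] = np.where(hit, rem, 0)
            rem = np.where(hit, 0, rem)
        self._quads = None
        self._y = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, weights ``(n_in, n_out)``."""

    def __init__(self, n_in: int, n_out: int, rng=None, dtype=np.float32):
        self.n_in, self.n_out = n_in, n_out
        if rng is None:
            self.W = np.zeros((n_in, n_out), dtype=dtype)
        else:
            scale = np.sqrt(2.0 / n_in)
            self.W = (scale * rng.standard_normal((n_in, n_out))).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``labels`` are integer class indices.  Raises TrainingError on
    non-finite loss so the caller can report the epoch.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    if not np.isfinite(loss):
        raise TrainingError("non-finite training loss")
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype)


class SGDMomentum:
    """Classical momentum SGD over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.vel):
            v *= self.momentum
            v -= self.lr * g
            p += v
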