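"""Minimal CPU neural-network core for the boundary-detection FCN.

Implements exactly the pieces the encoder-decoder architecture needs:
3x3 "same" convolution (im2col), batch normalization, ReLU, 2x2 max-pooling
that records argmax indices, index-driven max-unpooling, a softmax with
class-weighted cross-entropy, and the Adam optimizer.  Everything is
float32, fully deterministic given a seeded generator, and written as
forward/backward layer objects so the encoder-decoder coupling (each
unpooling reuses the indices of its paired pooling layer) is explicit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "MaxUnpool2x2",
    "softmax",
    "weighted_cross_entropy",
    "Adam",
]


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) → (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    N, C, H, W = x.shape
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)


class Conv2D:
    """3x3 stride-1 same-padding convolution, He-normal initialized."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch * k * k)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.T + self.b
        if train:
            self._x = x
        return out.reshape(N, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        x = self._x
        N, C, H, W = x.shape
        d = dout.transpose(0, 2, 3, 1).reshape(N * H * W, self.out_ch)
        cols = _im2col(x, self.k)
        self.dW = (d.T @ cols).astype(np.float32)
        self.db = d.sum(axis=0).astype(np.float32)
        # grad wrt input = correlation of dout with spatially-flipped,
        # channel-transposed kernels — itself a same conv
        Wt = (
            self.W.reshape(self.out_ch, self.in_ch, self.k, self.k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.in_ch, self.out_ch * self.k * self.k)
        )
        dcols = _im2col(dout, self.k)
        dx = dcols @ Wt.T
        return dx.reshape(N, H, W, self.in_ch).transpose(0, 3, 1, 2)

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm2D:
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray):
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (
            inv[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
        return dx.astype(np.float32)

    def params(self):
        return [("gamma", self), ("beta", self)]


class ReLU:
    def forward(self, x, train: bool = False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class MaxPool2x2:
    """2x2 stride-2 max pooling; records the argmax index (0..3) per window."""

    def forward(self, x, train: bool = False):
        N, C, H, W = x.shape
        v = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(N, C, H // 2, W // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self.indices = idx.astype(np.uint8)
        self._in_shape = (N, C, H, W)
        return out

    def backward(self, dout):
        return MaxUnpool2x2.scatter(dout, self.indices, self._in_shape)

    def params(self):
        return []


class MaxUnpool2x2:
    """Places values at the argmax positions recorded by a paired pooling."""

    def __init__(self, pool: MaxPool2x2):
        self.pool = pool

    @staticmethod
    def scatter(y, idx, out_shape):
        N, C, H, W = out_shape
        v = np.zeros((N, C, H // 2, W // 2, 4), dtype=y.dtype)
        np.put_along_axis(v, idx[..., None].astype(np.intp), y[..., None], axis=-1)
        v = v.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return v.reshape(N, C, H, W)

    def forward(self, y, train: bool = False):
        return self.scatter(y, self.pool.indices, self.pool._in_shape)

    def backward(self, dout):
        N, C, H, W = dout.shape
        v = dout.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(N, C, H // 2, W // 2, 4)
        return np.take_along_axis(v, self.pool.indices[..., None].astype(np.intp), -1)[
            ..., 0
        ]

    def params(self):
        return []


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, w_boundary: float, boundary_class: int = 1
):
    """Mean class-weighted cross-entropy over all pixels.

    probs: (N, K, H, W) normalized class distribution per pixel;
    labels: (N, H, W) integer classes.  Boundary-class pixels get weight
    ``w_boundary``, others weight 1; the mean is over the pixel count.
    Returns (loss, grad wrt logits of a softmax producing ``probs``).
    """
    probs = np.asarray(probs)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("per-pixel class distributions must be normalized")
    n = labels.size
    w = np.where(labels == boundary_class, w_boundary, 1.0)
    p_true = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
    loss = float((w * -np.log(np.clip(p_true, 1e-12, None))).sum() / n)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    grad = (w[:, None] * (probs - onehot) / n).astype(np.float32)
    return loss, grad


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.items = []
        for layer in layers:
            for name, owner in layer.params():
                p = getattr(owner, name)
                self.items.append(
                    (name, owner, np.zeros_like(p), np.zeros_like(p))
                )
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, owner, m, v in self.items:
            g = getattr(owner, "d" + name)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p = getattr(owner, name)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
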