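"""Minimal NumPy deep-learning engine for small residual CNNs.

Implements exactly the pieces the nucleus classifier needs — 2D convolution
(im2col + matmul), batch normalization, ReLU, parameter-free residual
shortcuts, global average pooling and a fully connected head — with manual
backward passes and an Adam optimizer. Tensors are NCHW float32; all
randomness flows through an explicit ``numpy.random.Generator`` so builds
and training runs are deterministic given a seed.

This is a CPU engine sized for desk-scale experiments (hundreds of images
at 128 px); it favors clarity and determinism over throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "Linear", "relu", "Adam",
           "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (mean loss, dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


class Layer:
    """Base: layers expose params()/grads() aligned lists for the optimizer."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    # (n, oh, ow, c*k*k)
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * k * k)
    return np.ascontiguousarray(col), oh, ow


class Conv2d(Layer):
    """2D convolution with He-normal init; square kernel, symmetric padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c_in, h, w = x.shape
        col, oh, ow = _im2col(x, self.kernel, self.stride, self.pad)
        wmat = self.w.reshape(self.w.shape[0], -1)  # (c_out, c_in*k*k)
        out = col.reshape(-1, wmat.shape[1]) @ wmat.T + self.b
        out = out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (col, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, x_shape, oh, ow = self._cache
        n, c_in, h, w = x_shape
        c_out = self.w.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        colflat = col.reshape(-1, col.shape[-1])
        self.dw += (dflat.T @ colflat).reshape(self.w.shape)
        self.db += dflat.sum(axis=0)
        wmat = self.w.reshape(c_out, -1)
        dcol = (dflat @ wmat).reshape(n, oh, ow, c_in, self.kernel, self.kernel)
        # scatter back (col2im)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((n, c_in, hp, wp), dtype=np.float32)
        s, k = self.stride, self.kernel
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                    dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(1.0 / n_in),
                            size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.w

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Adam:
    """Adam optimizer over a flat list of parameter/gradient array pairs."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    @staticmethod
    def zero_grads(grads: list[np.ndarray]) -> None:
        for g in grads:
            g[...] = 0
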