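"""Minimal 3D neural-network layers in NumPy with explicit backprop.

All layers operate on float32 tensors of shape (batch, channels, X, Y, Z).
Each layer caches what its backward pass needs during ``forward`` and
exposes ``params`` / ``grads`` lists for the optimizer.  Convolutions use
an im2col lowering so the heavy lifting is a single BLAS matmul per layer,
which keeps desk-scale training tractable on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3D",
    "BatchNorm3D",
    "ReLU",
    "SpatialDropout",
    "AvgPool3D",
    "NearestUpsample3D",
    "Adam",
]


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _offsets(k: int):
    return [(ox, oy, oz) for ox in range(k) for oy in range(k) for oz in range(k)]


class Conv3D(Layer):
    """3D convolution with 'same' zero padding and optional dilation.

    Weight layout: (c_out, k³ * c_in), grouped per kernel offset so the
    im2col matrix can be assembled from 27 contiguous slice copies.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.d = kernel, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.dw, self.db]
        self._cols = None
        self._xshape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        bsz, c, nx, ny, nz = x.shape
        k, d = self.k, self.d
        p = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((bsz, k**3 * c, nx * ny * nz), dtype=np.float32)
        for i, (ox, oy, oz) in enumerate(_offsets(k)):
            sx, sy, sz = ox * d, oy * d, oz * d
            cols[:, i * c:(i + 1) * c] = xp[
                :, :, sx:sx + nx, sy:sy + ny, sz:sz + nz
            ].reshape(bsz, c, -1)
        return cols

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        cols = self._im2col(x)
        self._cols = cols if training else None
        self._xshape = x.shape
        y = np.matmul(self.w[None], cols) + self.b[None, :, None]
        return y.reshape(x.shape[0], self.c_out, *x.shape[2:])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        bsz, c, nx, ny, nz = self._xshape
        gy = grad.reshape(bsz, self.c_out, -1)
        self.dw[...] = np.einsum("bon,bkn->ok", gy, self._cols, optimize=True)
        self.db[...] = gy.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T[None], gy)  # (B, k3*c, N)
        k, d = self.k, self.d
        p = d * (k // 2)
        dxp = np.zeros((bsz, c, nx + 2 * p, ny + 2 * p, nz + 2 * p), dtype=np.float32)
        for i, (ox, oy, oz) in enumerate(_offsets(k)):
            sx, sy, sz = ox * d, oy * d, oz * d
            dxp[:, :, sx:sx + nx, sy:sy + ny, sz:sz + nz] += dcols[
                :, i * c:(i + 1) * c
            ].reshape(bsz, c, nx, ny, nz)
        self._cols = None
        return dxp[:, :, p:p + nx, p:p + ny, p:p + nz]


class BatchNorm3D(Layer):
    """Per-channel batch normalisation over batch and spatial axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = (0, 2, 3, 4)
        m = shape[0] * shape[2] * shape[3] * shape[4]
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = self.gamma[None, :, None, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv[None, :, None, None, None]
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0 if training else None
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class SpatialDropout(Layer):
    """Channel-wise (spatial) dropout: whole feature maps are zeroed."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        keep = (rng.random((x.shape[0], x.shape[1])) >= self.rate).astype(np.float32)
        self._mask = keep[:, :, None, None, None] / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class AvgPool3D(Layer):
    def __init__(self, factor: tuple[int, int, int] = (2, 2, 2)) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        fx, fy, fz = self.factor
        b, c, nx, ny, nz = x.shape
        if nx % fx or ny % fy or nz % fz:
            raise ValueError(
                f"spatial shape {(nx, ny, nz)} not divisible by pool factor {self.factor}"
            )
        self._inshape = x.shape
        return x.reshape(b, c, nx // fx, fx, ny // fy, fy, nz // fz, fz).mean(axis=(3, 5, 7))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        fx, fy, fz = self.factor
        scale = 1.0 / (fx * fy * fz)
        g = np.repeat(np.repeat(np.repeat(grad, fx, axis=2), fy, axis=3), fz, axis=4)
        return (g * scale).astype(np.float32)


class NearestUpsample3D(Layer):
    def __init__(self, factor: tuple[int, int, int] = (2, 2, 2)) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        fx, fy, fz = self.factor
        return np.repeat(np.repeat(np.repeat(x, fx, axis=2), fy, axis=3), fz, axis=4)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        fx, fy, fz = self.factor
        b, c, nx, ny, nz = grad.shape
        return grad.reshape(
            b, c, nx // fx, fx, ny // fy, fy, nz // fz, fz
        ).sum(axis=(3, 5, 7)).astype(np.float32)


class Adam:
    """Adam optimizer with optional decoupled-from-loss L2 penalty."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, l2_decay: float = 0.0) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.l2 = l2_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            geff = g + self.l2 * p if self.l2 else g
            m[...] = self.b1 * m + (1 - self.b1) * geff
            v[...] = self.b2 * v + (1 - self.b2) * geff**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
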