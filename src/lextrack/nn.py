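"""Minimal numpy neural-network kernels for the match-mismatch CNN.

Implements exactly the pieces the model needs — 1x1 (spatial) convolutions,
dilated temporal convolutions (kernel 3, zero 'same' padding), tanh,
per-channel cosine similarity over time, a sigmoid/BCE head — with explicit
forward/backward passes and an Adam optimizer. Shapes follow the (batch,
channels, time) convention.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv1x1:
    """Pointwise channel mixing: y[b,f,t] = sum_c W[f,c] x[b,c,t] + b[f]."""

    def __init__(
        self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32
    ):
        scale = np.sqrt(1.0 / in_ch)
        self.w = Param(rng.uniform(-scale, scale, size=(out_ch, in_ch)).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.matmul(self.w.value, x) + self.b.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.tensordot(dy, self._x, axes=([0, 2], [0, 2]))
        self.b.grad += dy.sum(axis=(0, 2))
        return np.matmul(self.w.value.T, dy)


class DilatedConv1d:
    """Kernel-3 dilated convolution with zero 'same' padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        dilation: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.k = 3
        self.d = dilation
        scale = np.sqrt(1.0 / (in_ch * self.k))
        self.w = Param(
            rng.uniform(-scale, scale, size=(out_ch, in_ch, self.k)).astype(dtype)
        )
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, t = self.d, x.shape[2]
        xp = np.pad(x, [(0, 0), (0, 0), (d, d)])
        self._xp = xp
        y = np.broadcast_to(
            self.b.value[:, None], (x.shape[0], self.b.value.size, t)
        ).copy()
        for k in range(self.k):
            y += np.matmul(self.w.value[:, :, k], xp[:, :, k * d : k * d + t])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, t = self.d, dy.shape[2]
        dxp = np.zeros_like(self._xp)
        for k in range(self.k):
            xk = self._xp[:, :, k * d : k * d + t]
            self.w.grad[:, :, k] += np.tensordot(dy, xk, axes=([0, 2], [0, 2]))
            dxp[:, :, k * d : k * d + t] += np.matmul(self.w.value[:, :, k].T, dy)
        self.b.grad += dy.sum(axis=(0, 2))
        return dxp[:, :, d:-d]


class Tanh:
    def __init__(self):
        self._y: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class CosineOverTime:
    """Cosine similarity along time, per (batch, channel): (B,P,T),(B,P,T) ->
    (B,P)."""

    eps = 1e-8

    def forward(self, e: np.ndarray, s: np.ndarray) -> np.ndarray:
        self._e, self._s = e, s
        self._ne = np.sqrt((e**2).sum(axis=2)) + self.eps
        self._ns = np.sqrt((s**2).sum(axis=2)) + self.eps
        self._dot = (e * s).sum(axis=2)
        return self._dot / (self._ne * self._ns)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ne, ns, dot = self._ne, self._ns, self._dot
        c = dy / (ne * ns)
        de = c[:, :, None] * self._s - (dy * dot / (ne**3 * ns))[:, :, None] * self._e
        ds = c[:, :, None] * self._e - (dy * dot / (ne * ns**3))[:, :, None] * self._s
        return de, ds


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(p: np.ndarray, targets: np.ndarray) -> float:
    eps = 1e-12
    return float(
        -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    )


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
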