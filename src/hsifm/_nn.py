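"""Minimal 1-D neural-network layers with explicit backprop, in NumPy.

The inference model here is tiny (a few thousand parameters over 96-band
spectra), so layers are written directly: each holds its weights, computes
forward activations with caching, and accumulates parameter gradients on
backward. Spatial loops run over the (short, <=96) spectral axis; the batch
and channel contractions are tensordot calls. An Adam optimizer updates a
flat parameter list. Everything is float32 and deterministic for a fixed
seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A weight array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _f32(w: np.ndarray) -> np.ndarray:
    # weights may be stored as float16 after quantization; compute in fp32
    return np.asarray(w, dtype=np.float32)


class Conv1d:
    """Cross-correlation along the spectral axis. Input (N, C_in, L)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        self.p = (kernel - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def out_len(self, L: int) -> int:
        return (L + 2 * self.p - self.k) // self.s + 1

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        N, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p)))
        Lout = self.out_len(L)
        w, b = _f32(self.w.value), _f32(self.b.value)
        y = np.empty((N, self.c_out, Lout), dtype=np.float32)
        for j in range(Lout):
            seg = xp[:, :, j * self.s : j * self.s + self.k]
            y[:, :, j] = np.tensordot(seg, w, axes=([1, 2], [1, 2])) + b
        if cache:
            self._xp, self._L = xp, L
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        w = _f32(self.w.value)
        gxp = np.zeros_like(xp)
        self.b.grad += gy.sum(axis=(0, 2))
        for j in range(gy.shape[2]):
            seg = xp[:, :, j * self.s : j * self.s + self.k]
            g = gy[:, :, j]  # (N, C_out)
            self.w.grad += np.tensordot(g, seg, axes=(0, 0))
            gxp[:, :, j * self.s : j * self.s + self.k] += np.tensordot(
                g, w, axes=(1, 0)
            )
        return gxp[:, :, self.p : self.p + L] if self.p else gxp

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ConvTranspose1d:
    """Stride-s upsampling convolution; with pad=(k-1)//2, out_pad=1, s=2 it
    exactly doubles the length. Weight shape (C_in, C_out, k)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 2,
        pad: int | None = None,
        out_pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        self.p = (kernel - 1) // 2 if pad is None else pad
        self.op = out_pad
        if self.op > self.p:
            raise ValueError("output padding must not exceed padding")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param(rng.normal(0.0, scale, size=(c_in, c_out, kernel)))
        self.b = Param(np.zeros(c_out))

    def out_len(self, L: int) -> int:
        return (L - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        N, C, L = x.shape
        Lout = self.out_len(L)
        w, b = _f32(self.w.value), _f32(self.b.value)
        yfull = np.zeros((N, self.c_out, (L - 1) * self.s + self.k), dtype=np.float32)
        for i in range(L):
            yfull[:, :, i * self.s : i * self.s + self.k] += np.tensordot(
                x[:, :, i], w, axes=(1, 0)
            )
        y = yfull[:, :, self.p : self.p + Lout] + b[:, None]
        if cache:
            self._x, self._Lout = x, Lout
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, Lout = self._x, self._Lout
        N, C, L = x.shape
        w = _f32(self.w.value)
        gyfull = np.zeros((N, self.c_out, (L - 1) * self.s + self.k), dtype=np.float32)
        gyfull[:, :, self.p : self.p + Lout] = gy
        self.b.grad += gy.sum(axis=(0, 2))
        gx = np.empty_like(x)
        for i in range(L):
            seg = gyfull[:, :, i * self.s : i * self.s + self.k]  # (N, C_out, k)
            gx[:, :, i] = np.tensordot(seg, w, axes=([1, 2], [1, 2]))
            self.w.grad += np.tensordot(x[:, :, i], seg, axes=(0, 0))
        return gx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Dense:
    """Affine map on (N, n_in)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if cache:
            self._x = x
        return x @ _f32(self.w.value).T + _f32(self.b.value)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ _f32(self.w.value)

    def params(self) -> list[Param]:
        return [self.w, self.b]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(gy: np.ndarray, y: np.ndarray) -> np.ndarray:
    return gy * (y > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(z: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy of sigmoid(z) against a constant target,
    computed stably from logits."""
    z = np.asarray(z, dtype=np.float64)
    # log(1+e^z) stable: max(z,0) + log1p(e^{-|z|})
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(softplus - target * z))


def bce_grad(z: np.ndarray, target: float) -> np.ndarray:
    """d(mean BCE)/dz = (sigmoid(z) - target) / n_elements."""
    return (sigmoid(z) - target) / z.size


class Adam:
    """Adaptive-moment gradient descent over a Param list."""

    def __init__(self, params: list[Param], lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float32) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
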