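"""NumPy building blocks with forward/backward passes.

All tensors are NHWC float32/float64.  Convolutions use "same" padding with
ceiling division on stride (TensorFlow convention: the extra padding row/
column goes on the bottom/right), implemented as a sum over kernel taps so
each tap is a single matmul — fast enough for desk-scale training without a
deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "DepthwiseConv2D", "BatchNorm", "ReLU6", "truncated_normal"]


def truncated_normal(rng: np.random.Generator, shape, stddev: float = 0.03) -> np.ndarray:
    """Normal samples re-drawn until within 2 standard deviations."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > 2.0
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > 2.0
    return (out * stddev).astype(np.float32)


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """(pad_before, pad_after, out_size) for same-ceil padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    before = total // 2
    return before, total - before, out


class Conv2D:
    """Standard convolution, kernel ``(kh, kw, cin, cout)``, optional bias."""

    def __init__(self, kernel: np.ndarray, stride: int = 1, bias: np.ndarray | None = None):
        self.w = np.asarray(kernel, dtype=np.float32)
        self.b = None if bias is None else np.asarray(bias, dtype=np.float32)
        self.stride = stride
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def parameters(self) -> dict[str, np.ndarray]:
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        kh, kw, cin, cout = self.w.shape
        n, h, wdt, c = x.shape
        if c != cin:
            raise ValueError(f"expected {cin} input channels, got {c}")
        pt, pb, ho = _same_pad(h, kh, self.stride)
        pl, pr, wo = _same_pad(wdt, kw, self.stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        y = np.zeros((n, ho, wo, cout), dtype=x.dtype)
        s = self.stride
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
                y += patch @ self.w[i, j]
        if self.b is not None:
            y += self.b
        if training:
            self._cache = (xp, (pt, pl), x.shape, (ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (pt, pl), xshape, (ho, wo) = self._cache
        kh, kw, cin, cout = self.w.shape
        s = self.stride
        dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
                dw[i, j] = np.einsum("nhwc,nhwo->co", patch, dy, optimize=True)
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += dy @ self.w[i, j].T
        self.grads["w"] = dw
        if self.b is not None:
            self.grads["b"] = dy.sum(axis=(0, 1, 2))
        _, h, wdt, _ = xshape
        return dxp[:, pt:pt + h, pl:pl + wdt, :]


class DepthwiseConv2D:
    """One spatial filter per input channel, kernel stored as ``(kh, kw, c)``."""

    def __init__(self, kernel: np.ndarray, stride: int = 1):
        self.w = np.asarray(kernel, dtype=np.float32)
        self.stride = stride
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def parameters(self) -> dict[str, np.ndarray]:
        return {"w": self.w}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        kh, kw, cin = self.w.shape
        n, h, wdt, c = x.shape
        if c != cin:
            raise ValueError(f"expected {cin} input channels, got {c}")
        pt, pb, ho = _same_pad(h, kh, self.stride)
        pl, pr, wo = _same_pad(wdt, kw, self.stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        y = np.zeros((n, ho, wo, cin), dtype=x.dtype)
        s = self.stride
        for i in range(kh):
            for j in range(kw):
                y += xp[:, i:i + s * ho:s, j:j + s * wo:s, :] * self.w[i, j]
        if training:
            self._cache = (xp, (pt, pl), x.shape, (ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (pt, pl), xshape, (ho, wo) = self._cache
        kh, kw, cin = self.w.shape
        s = self.stride
        dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
                dw[i, j] = (patch * dy).sum(axis=(0, 1, 2))
                dxp[:, i:i + s * ho:s, j:j + s * wo:s, :] += dy * self.w[i, j]
        self.grads["w"] = dw
        _, h, wdt, _ = xshape
        return dxp[:, pt:pt + h, pl:pl + wdt, :]


class BatchNorm:
    """Per-channel batch normalisation with trainable scale/shift."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def parameters(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return (self.gamma * xhat + self.beta).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        return dx.astype(dy.dtype)


class ReLU6:
    """min(max(x, 0), 6) — zero-preserving, bounded for low-bit deployment."""

    def __init__(self) -> None:
        self.grads: dict[str, np.ndarray] = {}
        self._mask = None

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask
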