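"""Minimal numpy compute backend: layers with explicit forward/backward.

All tensors are channel-first ``(C, H, W)`` float64 arrays.  Each layer
caches what its backward pass needs on ``forward`` and releases it on
``backward``; networks are tiny (tens of thousands of parameters) so the
simplicity of float64 + caching is preferred over speed tricks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "Pool2",
    "Upsample2",
    "Concat",
    "xavier_uniform",
    "sigmoid",
    "Adam",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/xavier uniform init for a conv weight (Cout, Cin, k, k)."""
    cout, cin, kh, kw = shape
    fan_in = cin * kh * kw
    fan_out = cout * kh * kw
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class; layers with no parameters inherit the empty ``params``."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, *xs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray):  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2-D convolution (stride 1, odd kernel), bias included.

    Implemented as an im2col contraction; the zero padding of (k-1)/2 on
    every side preserves the spatial size, which is the property the whole
    full-resolution encoder relies on.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.W = np.zeros((out_channels, in_channels, kernel, kernel))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._win: np.ndarray | None = None

    def init_weights(self, rng: np.random.Generator) -> None:
        self.W = xavier_uniform(rng, self.W.shape)
        self.b = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[0]}"
            )
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        # windows: (Cin, H, W, k, k)
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(1, 2))
        self._win = win
        y = np.tensordot(self.W, win, axes=([1, 2, 3], [0, 3, 4]))
        return y + self.b[:, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        win = self._win
        self._win = None
        self.gW += np.tensordot(gy, win, axes=([1, 2], [1, 2]))
        self.gb += gy.sum(axis=(1, 2))
        # grad wrt input: full correlation with the flipped kernel
        p = self.kernel // 2
        gp = np.pad(gy, ((0, 0), (p, p), (p, p)))
        gwin = sliding_window_view(gp, (self.kernel, self.kernel), axis=(1, 2))
        Wf = self.W[:, :, ::-1, ::-1]
        return np.tensordot(
            Wf.transpose(1, 0, 2, 3), gwin, axes=([1, 2, 3], [0, 3, 4])
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return np.where(m, gy, 0.0)


class Pool2(Layer):
    """2x2 pooling with stride 2 (max or average); requires even H, W."""

    def __init__(self, kind: str = "max"):
        if kind not in ("max", "average"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.kind = kind

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("pooling requires even spatial dimensions")
        # (c, h2, w2, 4): each 2x2 block flattened in its last axis
        blocks = (
            x.reshape(c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h // 2, w // 2, 4)
        )
        if self.kind == "average":
            self._shape = x.shape
            return blocks.mean(axis=-1)
        y = blocks.max(axis=-1)
        mask = blocks == y[..., None]
        # break ties: keep only the first max in each 2x2 block
        self._argmask = mask & (np.cumsum(mask, axis=-1) == 1)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.kind == "average":
            c, h, w = self._shape
            return np.repeat(np.repeat(gy, 2, axis=1), 2, axis=2) / 4.0
        c, h2, w2, _ = self._argmask.shape
        g = self._argmask * gy[..., None]
        self._argmask = None
        return (
            g.reshape(c, h2, w2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h2 * 2, w2 * 2)
        )


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners off).

    Output sample i reads source coordinate (i + 0.5) * n_in / n_out - 0.5,
    clipped at the borders.
    """
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - frac
        A[i, hi_c] += frac
    return A


class Upsample2(Layer):
    """Spatial x2 upsampling, bilinear (default) or nearest."""

    def __init__(self, mode: str = "bilinear"):
        if mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _bilinear_matrix(2 * n_in, n_in)
        return self._mats[n_in]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "nearest":
            self._in_shape = x.shape
            return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
        c, h, w = x.shape
        self._in_shape = x.shape
        Ah, Aw = self._mat(h), self._mat(w)
        return np.einsum("ij,cjk,lk->cil", Ah, x, Aw, optimize=True)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        if self.mode == "nearest":
            return gy.reshape(c, h, 2, w, 2).sum(axis=(2, 4))
        Ah, Aw = self._mat(h), self._mat(w)
        return np.einsum("ji,cjk,kl->cil", Ah, gy, Aw, optimize=True)


class Concat(Layer):
    """Channel-wise concatenation of any number of same-size maps."""

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        self._sizes = [x.shape[0] for x in xs]
        return np.concatenate(xs, axis=0)

    def backward(self, gy: np.ndarray) -> list[np.ndarray]:
        out, at = [], 0
        for s in self._sizes:
            out.append(gy[at : at + s])
            at += s
        return out


class Adam:
    """ADAM optimizer over a flat dict of parameter arrays (updates in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
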