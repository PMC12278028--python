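"""Minimal numpy layers with explicit forward/backward passes.

Each layer exposes ``forward(x) -> (out, cache)`` and
``backward(dout, cache) -> dx``; parameter gradients accumulate into
``layer.grads`` so the Siamese branches can share one weight set (three
forward/backward passes per step, summed gradients).

Activations flow in NHWC layout (batch, freq, time, channels): with
channels innermost, the im2col gather is near-sequential and 1x1
convolutions collapse to plain matrix products, which keeps the small
spectrogram images (≈80 x 19) fast on one CPU core.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Layer",
    "Conv2dSame",
    "ReLU",
    "AvgPoolSame3",
    "Downsample2",
    "TimeMeanFreqPool",
    "Linear",
    "L2Normalize",
]


class Layer:
    """Base class: layers without parameters reuse these no-ops."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return getattr(self, "_grads", {})

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0


class Conv2dSame(Layer):
    """Stride-1 2-D convolution with zero 'same' padding, NHWC layout.

    Implemented as im2col + one BLAS matmul; the input gradient is the
    same-padded correlation of the output gradient with the flipped
    kernels (a second im2col + matmul, no scatter loops).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float64):
        fan_in = c_in * k * k
        # kernel stored as (k, k, C_in, C_out) to match the NHWC column order
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}

    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    @staticmethod
    def _cols(x: np.ndarray, k: int) -> np.ndarray:
        """Same-padded im2col: (N, H, W, C) -> (N*H*W, k*k*C)."""
        n, h, w_, c = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C) -> flat
        return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w_, k * k * c)

    def forward(self, x: np.ndarray):
        n, h, w_, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.k == 1:
            out = x @ self.w[0, 0] + self.b
            return out, x
        cols = self._cols(x, self.k)
        out = cols @ self.w.reshape(-1, self.c_out) + self.b
        return out.reshape(n, h, w_, self.c_out), x

    def backward(self, dout: np.ndarray, x: np.ndarray, need_dx: bool = True):
        n, h, w_, _ = dout.shape
        if self.k == 1:
            xm = x.reshape(-1, self.c_in)
            dm = dout.reshape(-1, self.c_out)
            self._grads["w"][0, 0] += xm.T @ dm
            self._grads["b"] += dm.sum(axis=0)
            return (dm @ self.w[0, 0].T).reshape(x.shape) if need_dx else None
        cols = self._cols(x, self.k)
        dmat = dout.reshape(-1, self.c_out)
        self._grads["w"] += (cols.T @ dmat).reshape(self.w.shape)
        self._grads["b"] += dmat.sum(axis=0)
        if not need_dx:
            return None
        # input gradient: correlate dout with spatially flipped kernels
        wflip = self.w[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.c_in)
        dx = self._cols(dout, self.k) @ wflip
        return dx.reshape(x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return dout * mask


class AvgPoolSame3(Layer):
    """3x3 stride-1 average pooling with zero padding (self-adjoint)."""

    _size = (1, 3, 3, 1)

    def forward(self, x: np.ndarray):
        return ndimage.uniform_filter(x, size=self._size, mode="constant"), None

    def backward(self, dout: np.ndarray, _cache) -> np.ndarray:
        return ndimage.uniform_filter(dout, size=self._size, mode="constant")


class Downsample2(Layer):
    """Non-overlapping 2x2 average pooling; trailing odd rows are dropped."""

    def forward(self, x: np.ndarray):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
        return xv.mean(axis=(2, 4)), (h, w)

    def backward(self, dout: np.ndarray, shape) -> np.ndarray:
        h, w = shape
        n, h2, w2, c = dout.shape
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        view = dx[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
        view[...] = dout[:, :, None, :, None] / 4.0
        return dx


class TimeMeanFreqPool(Layer):
    """Average over time, coarse-bin the frequency axis, flatten.

    Full global pooling would erase absolute frequency position — the
    very thing that separates EEG rhythms — so only the time axis is
    averaged; frequencies are reduced to ``n_bins`` coarse bands.
    """

    def __init__(self, n_bins: int):
        self.n_bins = n_bins

    def forward(self, x: np.ndarray):
        n, h, t, c = x.shape
        xm = x.mean(axis=2)  # (N, H, C)
        bounds = np.linspace(0, h, self.n_bins + 1).astype(int)
        pooled = np.stack(
            [xm[:, b0:b1].mean(axis=1) for b0, b1 in zip(bounds[:-1], bounds[1:])], axis=1
        )  # (N, n_bins, C)
        return pooled.reshape(n, -1), (n, h, t, c, bounds)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        n, h, t, c, bounds = cache
        dpool = dout.reshape(n, self.n_bins, c)
        dxm = np.empty((n, h, c), dtype=dout.dtype)
        for i, (b0, b1) in enumerate(zip(bounds[:-1], bounds[1:])):
            dxm[:, b0:b1] = dpool[:, i : i + 1] / (b1 - b0)
        return np.broadcast_to(dxm[:, :, None, :] / t, (n, h, t, c)).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float64):
        self.w = rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_out, d_in)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self._grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}

    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray):
        return x @ self.w.T + self.b, x

    def backward(self, dout: np.ndarray, x: np.ndarray) -> np.ndarray:
        self._grads["w"] += dout.T @ x
        self._grads["b"] += dout.sum(axis=0)
        return dout @ self.w


class L2Normalize(Layer):
    """Row-wise projection onto the unit hypersphere."""

    eps = 1e-12

    def forward(self, x: np.ndarray):
        r = np.sqrt((x**2).sum(axis=1, keepdims=True)) + self.eps
        y = x / r
        return y, (y, r)

    def backward(self, dout: np.ndarray, cache) -> np.ndarray:
        y, r = cache
        return (dout - y * (y * dout).sum(axis=1, keepdims=True)) / r
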