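"""The Siamese inception embedder.

One inception block runs four parallel branches over the spectrogram
image — 1x1, 3x3 and 5x5 convolutions plus a 3x3-average-pool + 1x1
convolution branch — concatenates them along channels and applies ReLU.
Blocks are separated by 2x2 average downsampling.  The head averages
over time, coarse-bins the frequency axis, and maps linearly into the
embedding space, where an explicit L2 normalization projects every
output onto the unit hypersphere.  All three triplet branches share
this single weight set.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from neuromap.embedding.layers import (
    AvgPoolSame3,
    Conv2dSame,
    Downsample2,
    L2Normalize,
    Linear,
    ReLU,
    TimeMeanFreqPool,
)

__all__ = ["InceptionBlock", "SphereEmbedder", "build_model"]


class InceptionBlock:
    """Parallel 1x1 / 3x3 / 5x5 / pooled-1x1 branches, concatenated."""

    def __init__(self, c_in: int, base: int, rng: np.random.Generator, dtype=np.float64):
        self.conv1 = Conv2dSame(c_in, base, 1, rng, dtype)
        self.conv3 = Conv2dSame(c_in, base, 3, rng, dtype)
        self.conv5 = Conv2dSame(c_in, base, 5, rng, dtype)
        self.pool = AvgPoolSame3()
        self.convp = Conv2dSame(c_in, base, 1, rng, dtype)
        self.relu = ReLU()
        self.base = base
        self.c_out = 4 * base

    @property
    def layers(self):
        return [self.conv1, self.conv3, self.conv5, self.convp]

    def forward(self, x: np.ndarray):
        o1, c1 = self.conv1.forward(x)
        o3, c3 = self.conv3.forward(x)
        o5, c5 = self.conv5.forward(x)
        pooled, _ = self.pool.forward(x)
        op, cp = self.convp.forward(pooled)
        out = np.concatenate([o1, o3, o5, op], axis=3)
        out, mask = self.relu.forward(out)
        return out, (c1, c3, c5, cp, mask)

    def backward(self, dout: np.ndarray, cache, need_dx: bool = True):
        c1, c3, c5, cp, mask = cache
        dout = self.relu.backward(dout, mask)
        b = self.base
        d1 = self.conv1.backward(dout[..., :b], c1, need_dx)
        d3 = self.conv3.backward(dout[..., b : 2 * b], c3, need_dx)
        d5 = self.conv5.backward(dout[..., 2 * b : 3 * b], c5, need_dx)
        dp = self.convp.backward(dout[..., 3 * b :], cp, need_dx)
        if not need_dx:
            return None
        return d1 + d3 + d5 + self.pool.backward(dp, None)


class SphereEmbedder:
    """CNN mapping (N, 4, F, T) spectrogram stacks to unit 128-D vectors."""

    def __init__(
        self,
        input_shape: tuple[int, int, int] = (4, 80, 19),
        embedding_dim: int = 128,
        blocks: int = 3,
        base_filters: int = 16,
        head_freq_bins: int = 8,
        seed: int = 0,
        dtype: str = "float32",
    ):
        if embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3BED)))
        self.input_shape = tuple(input_shape)
        self.embedding_dim = embedding_dim
        self.dtype = np.dtype(dtype).type
        self.config = {
            "input_shape": list(input_shape),
            "embedding_dim": embedding_dim,
            "blocks": blocks,
            "base_filters": base_filters,
            "head_freq_bins": head_freq_bins,
            "seed": seed,
            "dtype": dtype,
        }
        c, h, t = input_shape
        self.blocks: list[InceptionBlock] = []
        self.downs: list[Downsample2] = []
        for _ in range(blocks):
            blk = InceptionBlock(c, base_filters, rng, self.dtype)
            self.blocks.append(blk)
            self.downs.append(Downsample2())
            c = blk.c_out
            h, t = h // 2, t // 2
        self.head_pool = TimeMeanFreqPool(min(head_freq_bins, h))
        self.linear = Linear(c * self.head_pool.n_bins, embedding_dim, rng, self.dtype)
        self.norm = L2Normalize()

    # -- parameter plumbing -------------------------------------------------
    @property
    def _param_layers(self):
        layers = []
        for blk in self.blocks:
            layers.extend(blk.layers)
        layers.append(self.linear)
        return layers

    def n_params(self) -> int:
        return sum(p.size for lay in self._param_layers for p in lay.params().values())

    def zero_grad(self) -> None:
        for lay in self._param_layers:
            lay.zero_grad()

    def parameters(self):
        """Flat list of (array, grad) pairs in a stable order."""
        out = []
        for lay in self._param_layers:
            for name, p in lay.params().items():
                out.append((p, lay.grads[name]))
        return out

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (N, {', '.join(map(str, self.input_shape))}), got {x.shape}"
            )
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # NCHW -> NHWC
        caches = []
        for blk, down in zip(self.blocks, self.downs):
            x, c_blk = blk.forward(x)
            x, c_down = down.forward(x)
            caches.append((c_blk, c_down))
        x, c_head = self.head_pool.forward(x)
        x, c_lin = self.linear.forward(x)
        x, c_norm = self.norm.forward(x)
        caches.append((c_head, c_lin, c_norm))
        return x, caches

    def backward(self, dout: np.ndarray, caches) -> None:
        c_head, c_lin, c_norm = caches[-1]
        g = self.norm.backward(dout, c_norm)
        g = self.linear.backward(g, c_lin)
        g = self.head_pool.backward(g, c_head)
        n_blocks = len(self.blocks)
        for i, ((c_blk, c_down), blk, down) in enumerate(
            zip(reversed(caches[:-1]), reversed(self.blocks), reversed(self.downs))
        ):
            g = down.backward(g, c_down)
            g = blk.backward(g, c_blk, need_dx=(i < n_blocks - 1))

    def embed_batch(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out

    # -- persistence ----------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, lay in enumerate(self._param_layers):
            for name, p in lay.params().items():
                arrays[f"{i}_{name}"] = p
        np.savez(directory / "weights.npz", **arrays)
        (directory / "model.json").write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SphereEmbedder":
        directory = Path(directory)
        config = json.loads((directory / "model.json").read_text())
        keys = {"input_shape", "embedding_dim", "blocks", "base_filters",
                "head_freq_bins", "seed", "dtype"}
        extra = {k: v for k, v in config.items() if k not in keys}
        model = cls(
            input_shape=tuple(config["input_shape"]),
            embedding_dim=config["embedding_dim"],
            blocks=config["blocks"],
            base_filters=config["base_filters"],
            head_freq_bins=config["head_freq_bins"],
            seed=config["seed"],
            dtype=config.get("dtype", "float64"),
        )
        model.config.update(extra)
        with np.load(directory / "weights.npz") as npz:
            for i, lay in enumerate(model._param_layers):
                for name, p in lay.params().items():
                    p[...] = npz[f"{i}_{name}"]
        return model


def build_model(
    cfg, input_shape: tuple[int, int, int] = (4, 80, 19), dtype: str = "float32"
) -> SphereEmbedder:
    """Build a :class:`SphereEmbedder` from a :class:`TrainConfig`."""
    return SphereEmbedder(
        input_shape=input_shape,
        embedding_dim=cfg.embedding_dim,
        blocks=cfg.blocks,
        base_filters=cfg.base_filters,
        head_freq_bins=cfg.head_freq_bins,
        seed=cfg.seed,
        dtype=dtype,
    )
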