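"""Triplet sampling, the triplet loss, training loop, and inference.

The triplet generator mirrors the map's training protocol: an anchor
class is drawn uniformly from the available classes, anchor and positive
are two distinct segments of that class, and the negative comes from a
class drawn uniformly from the remainder.  Training minimizes the
FaceNet-form loss L = max(0, ‖a−p‖² − ‖a−n‖² + α) with Adam; on the
unit sphere the squared Euclidean distance is an affine function of
cosine distance, so the same geometry governs both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from neuromap.embedding.network import SphereEmbedder, build_model
from neuromap.preprocess import SpectroSegment

__all__ = [
    "Embedding",
    "TrainConfig",
    "Triplet",
    "sample_triplet",
    "triplet_loss",
    "prepare_inputs",
    "train",
    "embed",
]


@dataclass
class Embedding:
    """A unit-norm vector on the hypersphere plus provenance."""

    vector: np.ndarray
    patient_id: str
    start_time: float
    source_label: str | None = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        norm = np.linalg.norm(self.vector)
        if abs(norm - 1.0) > 1e-5:
            raise ValueError(f"embedding norm {norm} deviates from 1 by more than 1e-5")


@dataclass
class Triplet:
    anchor: SpectroSegment
    positive: SpectroSegment
    negative: SpectroSegment

    def __post_init__(self) -> None:
        if self.anchor.label != self.positive.label:
            raise ValueError("anchor and positive must share a class")
        if self.negative.label == self.anchor.label:
            raise ValueError("negative must come from a different class")


@dataclass
class TrainConfig:
    """Hyperparameters of the metric-learning stage.

    ``margin`` is the triplet margin α (squared-Euclidean scale).  The
    ``tiny`` preset (1 block, 8 base filters) is sized for CPU test
    runs; the default (3 blocks, 16 filters) for small studies.
    """

    margin: float = 0.2
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    blocks: int = 3
    base_filters: int = 16
    head_freq_bins: int = 8
    embedding_dim: int = 128
    triplets_per_epoch: int | None = None
    znorm: bool = True
    plateau_tol: float = 1e-3
    plateau_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        kw = dict(blocks=1, base_filters=8, epochs=8)
        kw.update(overrides)
        return cls(**kw)


def _group_by_class(dataset: list[SpectroSegment]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, seg in enumerate(dataset):
        if seg.label is None:
            raise ValueError("all segments must be labelled for triplet sampling")
        groups.setdefault(seg.label, []).append(i)
    return groups


def sample_triplet_indices(
    groups: dict[str, list[int]], rng: np.random.Generator
) -> tuple[int, int, int]:
    """Sample (anchor, positive, negative) dataset indices.

    Anchor class uniform over classes holding >= 2 segments; negative
    class uniform over all remaining classes.
    """
    anchor_classes = sorted(c for c, idx in groups.items() if len(idx) >= 2)
    if not anchor_classes:
        raise ValueError("need at least one class with >= 2 segments")
    if len(groups) < 2:
        raise ValueError("need at least 2 classes for triplet sampling")
    a_cls = anchor_classes[rng.integers(len(anchor_classes))]
    a_idx, p_idx = rng.choice(groups[a_cls], size=2, replace=False)
    neg_classes = sorted(c for c in groups if c != a_cls)
    n_cls = neg_classes[rng.integers(len(neg_classes))]
    n_idx = groups[n_cls][rng.integers(len(groups[n_cls]))]
    return int(a_idx), int(p_idx), int(n_idx)


def sample_triplet(dataset: list[SpectroSegment], rng: np.random.Generator) -> Triplet:
    """Sample one :class:`Triplet` from a labelled dataset."""
    groups = _group_by_class(dataset)
    a, p, n = sample_triplet_indices(groups, rng)
    return Triplet(dataset[a], dataset[p], dataset[n])


def triplet_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray, margin: float = 0.2) -> float:
    """L = max(0, ‖a−p‖² − ‖a−n‖² + α) for single unit-norm vectors."""
    d_ap = float(((a - p) ** 2).sum())
    d_an = float(((a - n) ** 2).sum())
    return max(0.0, d_ap - d_an + margin)


def prepare_inputs(segs: list[SpectroSegment], znorm: bool = True) -> np.ndarray:
    """Stack spectrograms into (N, 4, F, T), optionally z-scoring each
    channel image (mean 0, SD 1) — the network's input convention."""
    x = np.stack([s.spect for s in segs]).astype(float)
    if znorm:
        mu = x.mean(axis=(2, 3), keepdims=True)
        sd = x.std(axis=(2, 3), keepdims=True)
        x = (x - mu) / np.maximum(sd, 1e-8)
    return x


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params  # list of (value, grad)
        self.lr = lr
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_triplet_loss_and_grads(ea, ep, en, margin):
    """Mean loss over the batch and gradients w.r.t. the three embeddings."""
    d_ap = ((ea - ep) ** 2).sum(axis=1)
    d_an = ((ea - en) ** 2).sum(axis=1)
    per = np.maximum(0.0, d_ap - d_an + margin)
    active = (per > 0).astype(ea.dtype)[:, None]
    scale = np.asarray(2.0 / ea.shape[0], dtype=ea.dtype)
    ga = scale * (en - ep) * active
    gp = scale * (ep - ea) * active
    gn = scale * (ea - en) * active
    return float(per.mean()), ga, gp, gn


def train(
    model: SphereEmbedder,
    dataset: list[SpectroSegment],
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
) -> tuple[SphereEmbedder, list[float]]:
    """Train by triplet loss; returns the model and per-epoch mean loss.

    All randomness flows from ``cfg.seed``.  Training stops early once
    the relative improvement of the epoch loss stays below
    ``plateau_tol`` for ``plateau_patience`` consecutive epochs.
    """
    groups = _group_by_class(dataset)
    if len(groups) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    x_all = prepare_inputs(dataset, znorm=cfg.znorm)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7121)))
    opt = _Adam(model.parameters(), cfg.learning_rate)
    n_triplets = cfg.triplets_per_epoch or len(dataset)
    n_batches = max(1, int(np.ceil(n_triplets / cfg.batch_size)))

    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(n_batches):
            idx = np.array(
                [sample_triplet_indices(groups, rng) for _ in range(cfg.batch_size)]
            )
            xa, xp, xn = x_all[idx[:, 0]], x_all[idx[:, 1]], x_all[idx[:, 2]]
            ea, ca = model.forward(xa)
            ep_, cp = model.forward(xp)
            en, cn = model.forward(xn)
            loss, ga, gp, gn = _batch_triplet_loss_and_grads(ea, ep_, en, cfg.margin)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model.zero_grad()
            model.backward(ga, ca)
            model.backward(gp, cp)
            model.backward(gn, cn)
            opt.step()
            epoch_losses.append(loss)
        mean_loss = float(np.mean(epoch_losses))
        history.append(mean_loss)
        if checkpoint_dir is not None:
            model.save(checkpoint_dir)
            _save_train_state(checkpoint_dir, cfg, history)
        rel_improvement = (best - mean_loss) / max(best, 1e-12)
        if rel_improvement < cfg.plateau_tol:
            stale += 1
            if stale >= cfg.plateau_patience:
                break
        else:
            stale = 0
        best = min(best, mean_loss)
    return model, history


def _save_train_state(directory: str | Path, cfg: TrainConfig, history: list[float]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state = {"config": asdict(cfg), "loss_history": history}
    (directory / "training.json").write_text(json.dumps(state, indent=2))


def embed(
    model: SphereEmbedder,
    segs: list[SpectroSegment],
    batch_size: int = 64,
    znorm: bool = True,
) -> list[Embedding]:
    """Embed segments in order; batched, unit-norm outputs."""
    if not segs:
        return []
    x = prepare_inputs(segs, znorm=znorm)
    vectors = np.concatenate(
        [model.embed_batch(x[i : i + batch_size]) for i in range(0, len(segs), batch_size)]
    )
    return [
        Embedding(
            vector=v, patient_id=s.patient_id, start_time=s.start_time, source_label=s.label
        )
        for v, s in zip(vectors, segs)
    ]
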