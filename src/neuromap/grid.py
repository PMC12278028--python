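"""An approximately even coordinate grid on the unit hypersphere.

Points sampled i.i.d. from a standard normal and projected to the
sphere are evened out by repulsive (Riesz-type, inverse-square)
relaxation: each point moves along the tangential component of the
summed repulsion from its neighbors and is renormalized.  The grid then
serves as a fine-grained, class-free coordinate system: trajectories
are symbolized by nearest-coordinate assignment under cosine distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "SphereGrid",
    "sample_sphere",
    "relax",
    "nearest_coordinate",
    "assign",
    "used_coordinates",
    "nn_distance_cv",
]


@dataclass
class SphereGrid:
    """Unit-norm reference coordinates with dense integer IDs 0..n-1."""

    coords: np.ndarray  # (n, dim)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("all grid rows must be unit-norm within 1e-6")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "SphereGrid":
        with h5py.File(path, "r") as f:
            return cls(coords=f["coords"][()], meta=dict(f.attrs))


def sample_sphere(n: int, dim: int = 128, seed: int = 0) -> np.ndarray:
    """n i.i.d. uniform points on the unit (dim−1)-sphere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, dim))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    g = x @ x.T
    sq = np.maximum(np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g, 0.0)
    return sq


def _forces_full(x: np.ndarray):
    """Inverse-square repulsion summed over all other points.

    Returns (forces, energy) with energy = Σ_{i<j} 1/d_ij.
    """
    sq = _pairwise_sq_dists(x)
    np.fill_diagonal(sq, np.inf)
    d = np.sqrt(sq)
    inv3 = 1.0 / (d * sq)  # 1/d^3 so that (x_i - x_j)/d^3 has magnitude 1/d^2
    s = inv3.sum(axis=1)
    forces = x * s[:, None] - inv3 @ x
    energy = float((1.0 / d)[np.triu_indices_from(d, k=1)].sum())
    return forces, energy


def _forces_knn(x: np.ndarray, k: int, block: int = 1024):
    """k-nearest-neighbor truncated repulsion for large grids."""
    n = x.shape[0]
    forces = np.zeros_like(x)
    nn_dist = np.empty(n)
    for i0 in range(0, n, block):
        xb = x[i0 : i0 + block]
        sq = np.maximum(
            (xb**2).sum(1)[:, None] + (x**2).sum(1)[None, :] - 2 * xb @ x.T, 0.0
        )
        for r in range(xb.shape[0]):
            sq[r, i0 + r] = np.inf
        nn_idx = np.argpartition(sq, k, axis=1)[:, :k]
        rows = np.arange(xb.shape[0])[:, None]
        d = np.sqrt(sq[rows, nn_idx])
        nn_dist[i0 : i0 + xb.shape[0]] = d.min(axis=1)
        diffs = xb[:, None, :] - x[nn_idx]  # (b, k, dim)
        forces[i0 : i0 + xb.shape[0]] = (diffs / (d**3)[:, :, None]).sum(axis=1)
    return forces, nn_dist


def nn_distance_cv(x: np.ndarray) -> float:
    """Coefficient of variation of nearest-neighbor distances."""
    sq = _pairwise_sq_dists(x)
    np.fill_diagonal(sq, np.inf)
    nn = np.sqrt(sq.min(axis=1))
    return float(nn.std() / nn.mean())


def relax(
    points: np.ndarray,
    iterations: int = 200,
    step_initial: float = 0.1,
    step_final: float = 0.001,
    k_neighbors: int = 10,
    full_pairwise_max: int = 2000,
    seed: int = 0,
) -> SphereGrid:
    """Even out sphere points by repulsive relaxation.

    For n ≤ ``full_pairwise_max`` forces use all pairs and the total
    inverse-distance energy is kept non-increasing by step backtracking;
    larger grids use k-nearest-neighbor truncated forces.  The step size
    decays geometrically from ``step_initial`` to ``step_final`` (units
    of arc length per iteration).  The uniformity score recorded in the
    grid metadata is the coefficient of variation of nearest-neighbor
    distances before and after relaxation.
    """
    x = np.asarray(points, dtype=float).copy()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 points to relax")
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    n = x.shape[0]
    full = n <= full_pairwise_max

    # coincident points would produce infinite forces: jitter them apart
    if full:
        sq = _pairwise_sq_dists(x)
        np.fill_diagonal(sq, np.inf)
        if sq.min() < 1e-24:
            rng = np.random.default_rng(seed)
            x += rng.normal(0.0, 1e-6, size=x.shape)
            x /= np.linalg.norm(x, axis=1, keepdims=True)

    cv_initial = nn_distance_cv(x) if full else None
    decay = (step_final / step_initial) ** (1.0 / max(iterations - 1, 1))
    energy = None
    energy_history: list[float] = []
    if full:
        _, energy = _forces_full(x)
        energy_history.append(energy)
    for it in range(iterations):
        step = step_initial * decay**it
        if full:
            forces, _ = _forces_full(x)
        else:
            forces, _ = _forces_knn(x, min(k_neighbors, n - 1))
        # tangential, unit-normalized displacement direction per point
        forces = forces - (forces * x).sum(axis=1, keepdims=True) * x
        norms = np.linalg.norm(forces, axis=1, keepdims=True)
        direction = np.divide(forces, norms, out=np.zeros_like(forces), where=norms > 0)
        if full:
            # backtrack so the Riesz energy never increases
            trial_step = step
            for _ in range(8):
                x_new = x + trial_step * direction
                x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
                _, e_new = _forces_full(x_new)
                if e_new <= energy:
                    x, energy = x_new, e_new
                    break
                trial_step *= 0.5
            energy_history.append(energy)
        else:
            x = x + step * direction
            x /= np.linalg.norm(x, axis=1, keepdims=True)
    cv_final = nn_distance_cv(x) if full else None
    meta = {"iterations": iterations}
    if full:
        meta["cv_initial"] = cv_initial
        meta["cv_final"] = cv_final
        meta["energy_history"] = np.asarray(energy_history)
    return SphereGrid(coords=x, meta=meta)


def nearest_coordinate(vector: np.ndarray, grid: SphereGrid) -> int:
    """ID of the grid coordinate nearest in cosine distance.

    Exhaustive scan; exact ties resolve to the lowest ID.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (grid.dim,):
        raise ValueError(f"dimension mismatch: vector {v.shape} vs grid dim {grid.dim}")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero vector has no nearest coordinate")
    sims = grid.coords @ (v / nv)
    return int(np.argmax(sims))


def assign(vectors: np.ndarray, grid: SphereGrid, block: int = 4096) -> np.ndarray:
    """Vectorized nearest-coordinate assignment for many embeddings."""
    v = np.asarray(vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    ids = np.empty(v.shape[0], dtype=int)
    for i0 in range(0, v.shape[0], block):
        ids[i0 : i0 + block] = np.argmax(v[i0 : i0 + block] @ grid.coords.T, axis=1)
    return ids


def used_coordinates(assignments) -> int:
    """Number of distinct grid IDs actually occupied."""
    return len(set(np.asarray(assignments, dtype=int).tolist()))
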