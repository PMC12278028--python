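"""Long-term trajectories in the map and outcome prognostication.

A patient's recording becomes a time series of hypersphere embeddings
(one per 10-s segment), symbolized either by nearest class median or by
nearest grid coordinate.  Occupancy and dynamics features — notably
time in burst suppression, distance to the healthy continuum, and state
transition entropy — feed cross-validated SVM/LDA outcome classifiers
(good = CPC 1–2 vs poor = CPC 5), with patient- or center-level folds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from neuromap.embedding import embed
from neuromap.embedding.network import SphereEmbedder
from neuromap.grid import SphereGrid, assign
from neuromap.io import Recording
from neuromap.mapgeom import ClassMedianMap, cosine_distance, youden_point
from neuromap.preprocess import spectrograms_for_recording
from neuromap.synthetic import CLASSES, HEALTHY_CLASSES, IIIC_CLASSES

__all__ = [
    "Trajectory",
    "SymbolicSequence",
    "project_trajectory",
    "symbolize",
    "occupancy",
    "transition_entropy",
    "distance_to_healthy",
    "lz76_complexity",
    "dynamics_features",
    "outcome_classify",
    "lda_search",
    "group_occupancy_compare",
    "OutcomeResult",
]


@dataclass
class Trajectory:
    """Time-ordered unit-norm embeddings of one patient's recording."""

    patient_id: str
    timestamps: np.ndarray  # seconds, strictly increasing
    embeddings: np.ndarray  # (T, dim), rows unit-norm
    center_id: str | None = None
    outcome: str | None = None  # "good" (CPC 1-2) or "poor" (CPC 5)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if len(self.timestamps) != len(self.embeddings):
            raise ValueError("timestamps and embeddings must align")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.embeddings):
            norms = np.linalg.norm(self.embeddings, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-5):
                raise ValueError("trajectory rows must be unit-norm")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SymbolicSequence:
    """Integer symbol sequence over a class or grid-coordinate alphabet."""

    symbols: np.ndarray  # (T,) ints
    alphabet: list  # class names or grid ids
    source: str  # "class_median" | "grid" | "labels"

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if len(self.symbols) and not (
            self.symbols.min() >= 0 and self.symbols.max() < len(self.alphabet)
        ):
            raise ValueError("symbols outside alphabet")

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_labels(cls, labels: list[str], alphabet: list[str] | None = None) -> "SymbolicSequence":
        alphabet = list(alphabet or CLASSES)
        index = {c: i for i, c in enumerate(alphabet)}
        return cls(
            symbols=np.array([index[lab] for lab in labels], dtype=int),
            alphabet=alphabet,
            source="labels",
        )


def project_trajectory(model: SphereEmbedder, rec: Recording, **mt_kwargs) -> Trajectory:
    """Embed every non-overlapping 10-s segment of a recording in order."""
    spects = spectrograms_for_recording(rec, **mt_kwargs)
    if not spects:
        return Trajectory(
            patient_id=rec.patient_id,
            timestamps=np.empty(0),
            embeddings=np.empty((0, model.embedding_dim)),
            center_id=rec.center_id,
        )
    embs = embed(model, spects)
    return Trajectory(
        patient_id=rec.patient_id,
        timestamps=np.array([e.start_time for e in embs]),
        embeddings=np.stack([e.vector for e in embs]),
        center_id=rec.center_id,
    )


def symbolize(traj: Trajectory, reference: ClassMedianMap | SphereGrid) -> SymbolicSequence:
    """Assign each time point to its nearest reference vector.

    Nearest is by cosine distance; exact ties resolve to the lowest
    index.  The reference is either the 11 class medians or a sphere
    grid.
    """
    if isinstance(reference, ClassMedianMap):
        ref_vectors = reference.vectors
        alphabet: list = list(reference.classes)
        source = "class_median"
    else:
        ref_vectors = reference.coords
        alphabet = list(range(reference.n))
        source = "grid"
    if len(traj) == 0:
        return SymbolicSequence(np.empty(0, dtype=int), alphabet, source)
    if traj.embeddings.shape[1] != ref_vectors.shape[1]:
        raise ValueError("dimension mismatch between trajectory and reference")
    ref_unit = ref_vectors / np.linalg.norm(ref_vectors, axis=1, keepdims=True)
    sims = traj.embeddings @ ref_unit.T
    return SymbolicSequence(np.argmax(sims, axis=1), alphabet, source)


def occupancy(seq: SymbolicSequence) -> dict:
    """Fraction of time at each alphabet symbol (sums to 1)."""
    if len(seq) == 0:
        raise ValueError("occupancy undefined for an empty sequence")
    counts = np.bincount(seq.symbols, minlength=len(seq.alphabet))
    frac = counts / len(seq)
    return {seq.alphabet[i]: float(frac[i]) for i in range(len(seq.alphabet))}


def transition_entropy(seq: SymbolicSequence, base: float = 2.0) -> float:
    """First-order Markov entropy rate of the symbol sequence, in bits.

    H = −Σ_i π_i Σ_j P_ij log2 P_ij with the empirical transition matrix
    P and the empirical distribution π of positions 1..T−1.  States
    never visited contribute zero.
    """
    if len(seq) < 2:
        raise ValueError("transition entropy needs at least 2 symbols")
    k = len(seq.alphabet)
    s = seq.symbols
    counts = np.zeros((k, k))
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    row_tot = counts.sum(axis=1)
    pi = row_tot / row_tot.sum()
    h = 0.0
    for i in np.flatnonzero(row_tot):
        p = counts[i] / row_tot[i]
        nz = p > 0
        h -= pi[i] * (p[nz] * np.log(p[nz]) / np.log(base)).sum()
    return float(h)


def distance_to_healthy(
    traj: Trajectory, medians: ClassMedianMap, reduce: str = "mean"
) -> float:
    """Cosine distance to the nearest healthy-class median, per time point.

    The healthy continuum is {W, N1, N2, N3, REM}; per time point the
    minimum cosine distance over the five medians is taken and the
    feature is the ``reduce`` ("mean", "min" or "std") over time.
    """
    missing = [c for c in HEALTHY_CLASSES if c not in medians.classes]
    if missing:
        raise ValueError(f"median map lacks healthy classes: {missing}")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    ref = np.stack([medians.vector(c) for c in HEALTHY_CLASSES])
    ref = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    d = 1.0 - traj.embeddings @ ref.T  # (T, 5) cosine distances
    per_time = d.min(axis=1)
    return float({"mean": np.mean, "min": np.min, "std": np.std}[reduce](per_time))


def lz76_complexity(symbols: np.ndarray) -> int:
    """Lempel–Ziv (1976) phrase count of a symbol sequence.

    Sequential parsing into the minimal number of phrases, each being
    the shortest substring not seen in the prior history.
    """
    s = "".join(chr(48 + int(v)) for v in symbols)
    n = len(s)
    if n == 0:
        return 0
    # Kaspar–Schuster formulation of the 1976 parsing
    c, l, i, k, kmax = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] != s[l + k - 1]:
            kmax = max(kmax, k)
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i, k, kmax = 0, 1, 1
            else:
                k = 1
        else:
            k += 1
            if l + k > n:
                c += 1
                break
    return c


def _dwell_lengths(s: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(s) != 0)
    bounds = np.concatenate([[-1], change, [len(s) - 1]])
    return np.diff(bounds).astype(float)


def dynamics_features(
    seq: SymbolicSequence,
    traj: Trajectory | None = None,
    medians: ClassMedianMap | None = None,
    epoch_seconds: float = 10.0,
) -> dict[str, float]:
    """Registry of occupancy, symbolic-dynamics and spatial features.

    Symbolic features always computed: the 11 class occupancies (when
    the alphabet is the class list), aggregate time in burst
    suppression / healthy / IIIC states, transition entropy, transitions
    per hour, distinct symbol count, dwell-time statistics, and LZ-76
    complexity.  When a trajectory (and median map) is supplied, spatial
    features are added: distance-to-healthy statistics, mean cosine
    distance to each class median, path length, and step-size moments.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    feats: dict[str, float] = {}
    s = seq.symbols
    occ = occupancy(seq)
    is_class_alphabet = list(seq.alphabet) == CLASSES
    if is_class_alphabet:
        for cls in CLASSES:
            feats[f"occ_{cls}"] = occ[cls]
        feats["time_in_bs"] = occ["BS"]
        feats["time_in_healthy"] = float(sum(occ[c] for c in HEALTHY_CLASSES))
        feats["time_in_iiic"] = float(sum(occ[c] for c in IIIC_CLASSES))
    feats["n_distinct_symbols"] = float(len(np.unique(s)))
    n_trans = int((np.diff(s) != 0).sum())
    hours = len(s) * epoch_seconds / 3600.0
    feats["transitions_per_hour"] = n_trans / hours
    if len(s) >= 2:
        feats["transition_entropy"] = transition_entropy(seq)
    dwell = _dwell_lengths(s) * epoch_seconds
    feats["dwell_mean"] = float(dwell.mean())
    feats["dwell_sd"] = float(dwell.std())
    feats["dwell_max"] = float(dwell.max())
    feats["lz76"] = float(lz76_complexity(s))

    if traj is not None and len(traj):
        if medians is not None:
            feats["dist_healthy_mean"] = distance_to_healthy(traj, medians, "mean")
            feats["dist_healthy_min"] = distance_to_healthy(traj, medians, "min")
            feats["dist_healthy_sd"] = distance_to_healthy(traj, medians, "std")
            ref = medians.vectors / np.linalg.norm(medians.vectors, axis=1, keepdims=True)
            mean_d = (1.0 - traj.embeddings @ ref.T).mean(axis=0)
            for cls, d in zip(medians.classes, mean_d):
                feats[f"mean_dist_{cls}"] = float(d)
        if len(traj) >= 2:
            steps = 1.0 - (traj.embeddings[:-1] * traj.embeddings[1:]).sum(axis=1)
            feats["path_length"] = float(steps.sum())
            feats["step_mean"] = float(steps.mean())
            feats["step_sd"] = float(steps.std())
    return feats


@dataclass
class OutcomeResult:
    """Pooled cross-validated outcome-classification metrics."""

    auroc: float
    auroc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    fold_test_groups: list[set] = field(default_factory=list)


def _features_matrix(features: list[dict[str, float]], names: list[str] | None = None):
    if names is None:
        names = sorted(set().union(*[set(f) for f in features]))
    x = np.array([[f.get(name, 0.0) for name in names] for f in features])
    return x, names


def outcome_classify(
    features: list[dict[str, float]],
    outcomes: list[str],
    groups: list[str] | None = None,
    centers: list[str] | None = None,
    k: int = 5,
    group_by: str = "patient",
    n_boot: int = 1000,
    seed: int = 0,
) -> OutcomeResult:
    """Cross-validated SVM outcome classification (good vs poor).

    Folds split by patient (``group_by="patient"``, k folds) or one
    fold per clinical center (``group_by="center"``).  Decision scores
    are pooled across folds; the AUROC CI is a percentile bootstrap
    over ``n_boot`` patient-level resamples, and sensitivity/
    specificity are evaluated at the pooled Youden point.
    """
    y = np.array([1 if o == "poor" else 0 for o in outcomes])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome groups must be present")
    x, _ = _features_matrix(features)
    if group_by == "center":
        if centers is None:
            raise ValueError("center-level folds need center ids")
        fold_groups = np.asarray(centers)
        splitter = LeaveOneGroupOut()
    else:
        fold_groups = np.asarray(groups if groups is not None else np.arange(len(y)).astype(str))
        if len(set(fold_groups)) < k:
            raise ValueError("fewer patients than folds")
        splitter = GroupKFold(n_splits=k)

    scores = np.full(len(y), np.nan)
    fold_test_groups = []
    for train_idx, test_idx in splitter.split(x, y, fold_groups):
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("fold skipped: training side lacks an outcome class")
            continue
        fold_test_groups.append(set(fold_groups[test_idx]))
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", class_weight="balanced"))
        clf.fit(x[train_idx], y[train_idx])
        scores[test_idx] = clf.decision_function(x[test_idx])
    mask = np.isfinite(scores)
    y_eval, s_eval = y[mask], scores[mask]
    auroc = float(roc_auc_score(y_eval, s_eval))
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(len(y_eval), size=len(y_eval))
        if len(np.unique(y_eval[idx])) < 2:
            continue
        boot.append(roc_auc_score(y_eval[idx], s_eval[idx]))
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    thr, sens, spec = youden_point(y_eval, s_eval)
    return OutcomeResult(
        auroc=auroc,
        auroc_ci=ci,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
        fold_test_groups=fold_test_groups,
    )


def lda_search(
    features: list[dict[str, float]],
    outcomes: list[str],
    groups: list[str] | None = None,
    combo_sizes: tuple[int, ...] = (2, 3),
    k: int = 5,
    seed: int = 0,
) -> list[tuple[tuple[str, ...], float]]:
    """Exhaustive LDA search over feature pairs and triples.

    Every size-2 and size-3 feature combination is scored by the pooled
    cross-validated AUROC of its LDA discriminant score; the list is
    returned ranked descending.  Combinations with singular within-class
    covariance are skipped with a diagnostic warning.
    """
    y = np.array([1 if o == "poor" else 0 for o in outcomes])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome groups must be present")
    x, names = _features_matrix(features)
    if len(names) < 2:
        raise ValueError("need at least 2 features")
    fold_groups = np.asarray(groups if groups is not None else np.arange(len(y)).astype(str))
    splitter = GroupKFold(n_splits=min(k, len(set(fold_groups))))
    folds = list(splitter.split(x, y, fold_groups))

    results = []
    for size in combo_sizes:
        for combo in itertools.combinations(range(len(names)), size):
            xs = x[:, combo]
            scores = np.full(len(y), np.nan)
            try:
                for train_idx, test_idx in folds:
                    if len(np.unique(y[train_idx])) < 2:
                        continue
                    lda = make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
                    lda.fit(xs[train_idx], y[train_idx])
                    scores[test_idx] = lda.decision_function(xs[test_idx])
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"combo {tuple(names[i] for i in combo)} skipped: singular covariance"
                )
                continue
            mask = np.isfinite(scores)
            if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
                continue
            auroc = float(roc_auc_score(y[mask], scores[mask]))
            results.append((tuple(names[i] for i in combo), auroc))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


def group_occupancy_compare(
    features: list[dict[str, float]], outcomes: list[str]
) -> dict[str, float]:
    """Two-sided Mann–Whitney U between outcome groups.

    Compares healthy-state, IIIC-state and BS occupancy; returns a
    p-value per state group.
    """
    y = np.asarray(outcomes)
    out = {}
    for key in ("time_in_healthy", "time_in_iiic", "time_in_bs"):
        a = np.array([f[key] for f, o in zip(features, y) if o == "good"])
        b = np.array([f[key] for f, o in zip(features, y) if o == "poor"])
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each outcome group needs >= 2 patients")
        out[key] = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out
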