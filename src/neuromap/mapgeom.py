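"""Geometry and classification analytics of the embedding map.

Class medians are elementwise medians of each class's embeddings; their
pairwise cosine distances summarize the map's semantic layout and are
projected to 2-D by classical (Torgerson) multidimensional scaling.
Out-of-sample classification uses a patient-level cross-validated RBF
SVM with bootstrapped one-vs-rest ROC/PR curves and Youden operating
points chosen on training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from neuromap.embedding import Embedding
from neuromap.synthetic import CLASSES

__all__ = [
    "ClassMedianMap",
    "EvalReport",
    "cosine_distance",
    "class_medians",
    "median_distance_matrix",
    "mds_project",
    "classify_cv",
    "roc_pr_one_vs_all",
    "youden_point",
]


@dataclass
class ClassMedianMap:
    """Per-class elementwise-median reference vectors.

    Medians are deliberately not renormalized onto the sphere: all map
    geometry uses cosine distance, which is scale-free.
    """

    classes: list[str]
    vectors: np.ndarray  # (k, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("median vectors must be finite")
        if len(self.classes) != self.vectors.shape[0]:
            raise ValueError("one vector per class required")

    def vector(self, cls: str) -> np.ndarray:
        return self.vectors[self.classes.index(cls)]


@dataclass
class EvalReport:
    """Cross-validated classification metrics over the map."""

    classes: list[str]
    accuracy: float
    accuracy_sd: float
    macro_f1: float
    macro_f1_sd: float
    confusion_mean: np.ndarray  # row-normalized, (k, k)
    confusion_sd: np.ndarray
    youden: dict[str, dict[str, float]]
    fold_test_patients: list[set] = field(default_factory=list)
    roc_pr: dict[str, dict[str, object]] | None = None


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − cos∠(u, v); in [0, 2], zero iff the vectors are parallel."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 2.0))


def class_medians(embs: list[Embedding], classes: list[str] | None = None) -> ClassMedianMap:
    """Elementwise median embedding per class, in canonical class order.

    With ``classes=None`` the classes present in the data are used (in
    canonical order, unknown labels appended alphabetically); passing an
    explicit list makes an empty class an error naming that class.
    """
    by_class: dict[str, list[np.ndarray]] = {}
    for e in embs:
        if e.source_label is None:
            raise ValueError("embeddings must carry source labels")
        by_class.setdefault(e.source_label, []).append(e.vector)
    if classes is None:
        present = set(by_class)
        classes = [c for c in CLASSES if c in present] + sorted(present - set(CLASSES))
    for cls in classes:
        if not by_class.get(cls):
            raise ValueError(f"class {cls!r} has no embeddings")
    vectors = np.stack([np.median(np.stack(by_class[c]), axis=0) for c in classes])
    return ClassMedianMap(classes=list(classes), vectors=vectors)


def median_distance_matrix(medians: ClassMedianMap) -> np.ndarray:
    """Symmetric cosine-distance matrix between all class medians."""
    k = len(medians.classes)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = cosine_distance(medians.vectors[i], medians.vectors[j])
    return d


def mds_project(dist: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    the top-``dim`` coordinates.  Exact for distance matrices realizable
    in ``dim`` Euclidean dimensions (up to rotation/reflection); signs
    are fixed deterministically.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    pts = evecs[:, order] * np.sqrt(lam)
    # deterministic orientation: the largest-|.| entry of each axis is positive
    for k in range(pts.shape[1]):
        col = pts[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            pts[:, k] = -col
    return pts


def _embs_to_xy(embs: list[Embedding]):
    x = np.stack([e.vector for e in embs])
    y = np.array([e.source_label for e in embs])
    groups = np.array([e.patient_id for e in embs])
    return x, y, groups


def _default_svm() -> SVC:
    return SVC(kernel="rbf", class_weight="balanced", decision_function_shape="ovr")


def youden_point(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties in J are broken toward higher sensitivity.  Returns
    (threshold, sensitivity, specificity).
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("Youden point undefined for a single-class sample")
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(tpr[candidates])]
    return float(thresholds[best]), float(tpr[best]), float(1.0 - fpr[best])


def classify_cv(embs: list[Embedding], k: int = 5) -> EvalReport:
    """Patient-level k-fold SVM classification in the embedding space.

    Folds are split by patient (no patient appears in both the training
    and the test side of a fold).  The confusion matrix is
    row-normalized per fold and reported as mean ± SD; per-class Youden
    thresholds are chosen on the training folds and applied to the test
    folds for sensitivity/specificity.
    """
    x, y, groups = _embs_to_xy(embs)
    n_patients = len(set(groups))
    if n_patients < k:
        raise ValueError(f"need >= {k} patients for {k}-fold patient-level CV, got {n_patients}")
    classes = [c for c in CLASSES if c in set(y)] + sorted(set(y) - set(CLASSES))
    cv = GroupKFold(n_splits=k)
    accs, f1s, confs = [], [], []
    youden_acc: dict[str, list[tuple[float, float, float]]] = {c: [] for c in classes}
    fold_patients = []
    for train_idx, test_idx in cv.split(x, y, groups):
        assert not set(groups[train_idx]) & set(groups[test_idx])
        fold_patients.append(set(groups[test_idx]))
        clf = make_pipeline(StandardScaler(), _default_svm())
        clf.fit(x[train_idx], y[train_idx])
        pred = clf.predict(x[test_idx])
        accs.append(np.mean(pred == y[test_idx]))
        f1s.append(f1_score(y[test_idx], pred, labels=classes, average="macro", zero_division=0))
        cm = confusion_matrix(y[test_idx], pred, labels=classes).astype(float)
        rows = cm.sum(axis=1, keepdims=True)
        confs.append(np.divide(cm, rows, out=np.full_like(cm, np.nan), where=rows > 0))
        # Youden operating points: threshold from train scores, applied to test
        svm_classes = list(clf[-1].classes_)
        train_scores = clf.decision_function(x[train_idx])
        test_scores = clf.decision_function(x[test_idx])
        for c in classes:
            if c not in svm_classes:
                continue
            col = svm_classes.index(c)
            y_tr = (y[train_idx] == c).astype(int)
            y_te = (y[test_idx] == c).astype(int)
            if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                continue
            thr, _, _ = youden_point(y_tr, train_scores[:, col])
            pred_pos = test_scores[:, col] >= thr
            sens = float(pred_pos[y_te == 1].mean())
            spec = float((~pred_pos[y_te == 0]).mean())
            youden_acc[c].append((thr, sens, spec))
    youden = {
        c: {
            "threshold": float(np.mean([v[0] for v in vals])),
            "sensitivity": float(np.mean([v[1] for v in vals])),
            "specificity": float(np.mean([v[2] for v in vals])),
        }
        for c, vals in youden_acc.items()
        if vals
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        conf_mean = np.nanmean(np.stack(confs), axis=0)
        conf_sd = np.nanstd(np.stack(confs), axis=0)
    return EvalReport(
        classes=classes,
        accuracy=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs)),
        macro_f1=float(np.mean(f1s)),
        macro_f1_sd=float(np.std(f1s)),
        confusion_mean=conf_mean,
        confusion_sd=conf_sd,
        youden=youden,
        fold_test_patients=fold_patients,
    )


def roc_pr_one_vs_all(
    embs: list[Embedding],
    k: int = 5,
    n_boot: int = 50,
    seed: int = 0,
) -> dict[str, dict[str, object]]:
    """Per-class one-vs-rest AUROC/AUPR with bootstrap 95% CIs.

    Within each CV fold the test items are resampled with replacement
    ``n_boot`` times; CIs are the 2.5/97.5 percentiles of the pooled
    bootstrap values.  Folds whose test side lacks a class are skipped
    for that class with a warning.
    """
    x, y, groups = _embs_to_xy(embs)
    if len(set(groups)) < k:
        raise ValueError("fewer patients than folds")
    classes = [c for c in CLASSES if c in set(y)] + sorted(set(y) - set(CLASSES))
    rng = np.random.default_rng(seed)
    boot: dict[str, dict[str, list[float]]] = {
        c: {"auroc": [], "aupr": []} for c in classes
    }
    cv = GroupKFold(n_splits=k)
    for train_idx, test_idx in cv.split(x, y, groups):
        clf = make_pipeline(StandardScaler(), _default_svm())
        clf.fit(x[train_idx], y[train_idx])
        svm_classes = list(clf[-1].classes_)
        scores = clf.decision_function(x[test_idx])
        y_test = y[test_idx]
        for c in classes:
            if c not in svm_classes or len(np.unique(y_test == c)) < 2:
                warnings.warn(f"class {c!r} absent from a test fold; fold skipped")
                continue
            col = svm_classes.index(c)
            y_bin = (y_test == c).astype(int)
            s = scores[:, col]
            for _ in range(n_boot):
                idx = rng.integers(len(y_bin), size=len(y_bin))
                if len(np.unique(y_bin[idx])) < 2:
                    continue
                boot[c]["auroc"].append(roc_auc_score(y_bin[idx], s[idx]))
                boot[c]["aupr"].append(average_precision_score(y_bin[idx], s[idx]))
    out: dict[str, dict[str, object]] = {}
    for c in classes:
        res: dict[str, object] = {}
        for metric in ("auroc", "aupr"):
            vals = np.array(boot[c][metric])
            if vals.size == 0:
                res[metric] = None
                res[f"{metric}_ci"] = None
            else:
                res[metric] = float(vals.mean())
                res[f"{metric}_ci"] = (
                    float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)),
                )
        out[c] = res
    return out
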