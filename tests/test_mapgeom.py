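"""Map geometry and classification: cosine distance, medians, MDS,
patient-level CV, ROC/PR bootstrap, Youden points."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from neuromap.embedding import Embedding
from neuromap.mapgeom import (
    class_medians,
    classify_cv,
    cosine_distance,
    mds_project,
    median_distance_matrix,
    roc_pr_one_vs_all,
    youden_point,
)
from neuromap.synthetic import CLASSES


def _emb(v, pid="p0", label="W"):
    v = np.asarray(v, dtype=float)
    return Embedding(vector=v / np.linalg.norm(v), patient_id=pid,
                     start_time=0.0, source_label=label)


class TestCosineDistance:
    def test_identity(self):
        u = np.array([1.0, 0.0, 0.0])
        assert cosine_distance(u, u) == 0.0

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_antipodal(self):
        assert cosine_distance([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(2.0)

    def test_scale_invariant(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=5), rng.normal(size=5)
        assert cosine_distance(u, v) == pytest.approx(cosine_distance(3 * u, 0.2 * v))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))

    def test_relation_to_euclidean_on_unit_vectors(self):
        """On the sphere, cosine distance equals ||u-v||^2 / 2."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.normal(size=16), rng.normal(size=16)
            u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
            assert cosine_distance(u, v) == pytest.approx(((u - v) ** 2).sum() / 2)


class TestClassMedians:
    def test_single_embedding_is_its_own_median(self):
        e = _emb(np.ones(4), label="W")
        m = class_medians([e], classes=["W"])
        assert np.allclose(m.vector("W"), e.vector)

    def test_elementwise_median(self):
        vs = [[0.1, 1.0], [0.2, 1.0], [0.9, 1.0]]
        embs = [_emb(v, label="N1") for v in vs]
        m = class_medians(embs, classes=["N1"])
        # compare against brute-force per-coordinate median of the unit vectors
        stacked = np.stack([e.vector for e in embs])
        assert np.allclose(m.vector("N1"), np.median(stacked, axis=0))

    def test_symmetric_perturbations_cancel(self):
        e1 = np.zeros(8)
        e1[0] = 1.0
        rng = np.random.default_rng(2)
        delta = 0.05 * rng.normal(size=8)
        embs = [_emb(e1 + delta, label="W"), _emb(e1 - delta, label="W"),
                _emb(e1, label="W")]
        m = class_medians(embs, classes=["W"])
        d = m.vector("W") / np.linalg.norm(m.vector("W"))
        assert cosine_distance(d, e1) < 5e-3

    def test_empty_class_named_in_error(self):
        with pytest.raises(ValueError, match="REM"):
            class_medians([_emb(np.ones(4), label="W")], classes=["W", "REM"])


class TestDistanceMatrix:
    def test_identical_medians_have_zero_distance(self):
        """Two classes mapping to one point — like wake data from two
        sources landing at the same spot — give off-diagonal 0."""
        embs = [_emb([1, 0, 0], label="W"), _emb([1, 0, 0], label="N1"),
                _emb([0, 1, 0], label="N2")]
        m = class_medians(embs, classes=["W", "N1", "N2"])
        d = median_distance_matrix(m)
        assert d[0, 1] == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(3)
        embs = [_emb(rng.normal(size=16), label=c) for c in CLASSES for _ in range(3)]
        d = median_distance_matrix(class_medians(embs))
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_orthogonal_medians(self):
        embs = [_emb([1, 0, 0], label="W"), _emb([0, 1, 0], label="N1"),
                _emb([0, 0, 1], label="N2")]
        d = median_distance_matrix(class_medians(embs, classes=["W", "N1", "N2"]))
        off = d[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)


class TestMds:
    def test_equilateral(self):
        d = np.ones((3, 3)) - np.eye(3)
        pts = mds_project(d)
        rec = pdist(pts)
        assert np.allclose(rec, rec[0], atol=1e-6)
        assert rec[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_points(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        pts = mds_project(d)
        assert np.linalg.norm(pts[0] - pts[1]) == pytest.approx(0.7, abs=1e-9)

    def test_planar_round_trip(self):
        """Distances of random planar point sets are recovered to 1e-6."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            pts = rng.normal(size=(8, 2))
            d = squareform(pdist(pts))
            rec = mds_project(d, dim=2)
            assert np.abs(squareform(pdist(rec)) - d).max() < 1e-6

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            mds_project(d)


class TestClassifyCv:
    def test_separable_clusters_high_accuracy(self, clustered_embeddings):
        report = classify_cv(clustered_embeddings, k=5)
        assert report.accuracy >= 0.95
        assert report.macro_f1 >= 0.95

    def test_patient_partition(self, clustered_embeddings):
        report = classify_cv(clustered_embeddings, k=5)
        seen = set()
        for fold in report.fold_test_patients:
            assert not (fold & seen)
            seen |= fold

    def test_shuffled_labels_near_chance(self, clustered_embeddings):
        rng = np.random.default_rng(5)
        labels = [e.source_label for e in clustered_embeddings]
        shuffled = rng.permutation(labels)
        embs = [
            Embedding(vector=e.vector, patient_id=f"p{i}", start_time=0.0,
                      source_label=lab)
            for i, (e, lab) in enumerate(zip(clustered_embeddings, shuffled))
        ]
        report = classify_cv(embs, k=5)
        n = len(embs)
        p = 1 / 11
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(report.accuracy - p) < 3 * sd + 0.02

    def test_too_few_patients(self):
        embs = [_emb(np.ones(4), pid="only", label="W")] * 10
        with pytest.raises(ValueError):
            classify_cv(embs, k=5)

    def test_confusion_rows_sum_to_one(self, clustered_embeddings):
        report = classify_cv(clustered_embeddings, k=5)
        sums = np.nansum(report.confusion_mean, axis=1)
        assert np.allclose(sums, 1.0, atol=1e-8)


class TestRocPr:
    def test_perfect_scores(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        t, sens, spec = youden_point(y, y.astype(float))
        assert sens == 1.0 and spec == 1.0

    def test_useless_scores(self):
        y = np.array([0, 1, 0, 1])
        _, sens, spec = youden_point(y, np.ones(4))
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_youden_matches_brute_force(self):
        """6-point toy set: exhaustive threshold search gives the same J."""
        y = np.array([0, 0, 1, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.9])
        _, sens, spec = youden_point(y, s)
        best_j = -np.inf
        for thr in np.concatenate([s - 1e-9, s + 1e-9]):
            pred = s >= thr
            se = pred[y == 1].mean()
            sp = (~pred[y == 0]).mean()
            best_j = max(best_j, se + sp - 1)
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_point(np.zeros(5, dtype=int), np.arange(5.0))

    def test_auroc_equals_rank_statistic(self):
        """AUROC == Mann-Whitney concordance, checked by brute force."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.normal(size=30)
        pos, neg = s[y == 1], s[y == 0]
        conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert roc_auc_score(y, s) == pytest.approx(conc)

    def test_random_scores_near_half(self, clustered_embeddings):
        rng = np.random.default_rng(7)
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=1000)
        s = rng.normal(size=1000)
        assert 0.45 <= roc_auc_score(y, s) <= 0.55

    def test_bootstrap_report_structure(self, clustered_embeddings):
        out = roc_pr_one_vs_all(clustered_embeddings[:550], k=3, n_boot=10)
        for cls, res in out.items():
            if res["auroc"] is None:
                continue
            lo, hi = res["auroc_ci"]
            assert 0.0 <= lo <= res["auroc"] <= hi <= 1.0
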