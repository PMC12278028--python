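"""Trajectory symbolization, dynamics features, and outcome
classification."""

import numpy as np
import pytest

from neuromap.grid import SphereGrid, sample_sphere
from neuromap.mapgeom import ClassMedianMap
from neuromap.synthetic import CLASSES, HEALTHY_CLASSES
from neuromap.trajectory import (
    SymbolicSequence,
    Trajectory,
    distance_to_healthy,
    dynamics_features,
    group_occupancy_compare,
    lda_search,
    lz76_complexity,
    occupancy,
    outcome_classify,
    symbolize,
    transition_entropy,
)


def _median_map(dim=16, seed=0):
    vecs = sample_sphere(len(CLASSES), dim, seed=seed)
    return ClassMedianMap(classes=list(CLASSES), vectors=vecs)


def _traj(vectors, pid="p0"):
    vectors = np.asarray(vectors, dtype=float)
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return Trajectory(
        patient_id=pid,
        timestamps=10.0 * np.arange(len(vectors)),
        embeddings=vectors,
    )


def _seq(symbols, alphabet=None):
    return SymbolicSequence(
        symbols=np.asarray(symbols, dtype=int),
        alphabet=list(alphabet if alphabet is not None else CLASSES),
        source="labels",
    )


class TestSymbolize:
    def test_median_copies_map_to_their_class(self):
        m = _median_map()
        w = m.vector("W")
        traj = _traj(np.tile(w, (6, 1)))
        seq = symbolize(traj, m)
        assert all(m.classes[i] == "W" for i in seq.symbols)

    def test_matches_brute_force(self):
        m = _median_map(seed=3)
        pts = sample_sphere(500, 16, seed=4)
        seq = symbolize(_traj(pts), m)
        ref = m.vectors / np.linalg.norm(m.vectors, axis=1, keepdims=True)
        for k in range(0, 500, 23):
            dists = [1 - pts[k] @ r for r in ref]
            assert seq.symbols[k] == int(np.argmin(dists))

    def test_grid_and_class_sequences_have_equal_length(self):
        m = _median_map()
        g = SphereGrid(coords=sample_sphere(64, 16, seed=5))
        traj = _traj(sample_sphere(40, 16, seed=6))
        assert len(symbolize(traj, m)) == len(symbolize(traj, g)) == 40

    def test_empty_trajectory(self):
        m = _median_map()
        empty = Trajectory("p", np.empty(0), np.empty((0, 16)))
        assert len(symbolize(empty, m)) == 0


class TestOccupancy:
    def test_simple_fractions(self):
        seq = SymbolicSequence.from_labels(["BS", "BS", "W", "W"])
        occ = occupancy(seq)
        assert occ["BS"] == 0.5 and occ["W"] == 0.5

    def test_constant(self):
        occ = occupancy(SymbolicSequence.from_labels(["N2"] * 7))
        assert occ["N2"] == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        seq = _seq(rng.integers(0, 11, size=500))
        assert sum(occupancy(seq).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            occupancy(_seq([]))


class TestTransitionEntropy:
    def test_constant_sequence(self):
        assert transition_entropy(_seq([3] * 50)) == 0.0

    def test_strict_alternation(self):
        assert transition_entropy(_seq([0, 1] * 50)) == 0.0

    def test_iid_uniform_four_states(self):
        rng = np.random.default_rng(1)
        seq = _seq(rng.integers(0, 4, size=100_000), alphabet=list("ABCD"))
        assert transition_entropy(seq) == pytest.approx(2.0, abs=0.02)

    def test_bounded_by_log_alphabet(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            seq = _seq(rng.integers(0, 11, size=200))
            k = len(np.unique(seq.symbols))
            assert transition_entropy(seq) <= np.log2(max(k, 2)) + 1e-9

    def test_too_short(self):
        with pytest.raises(ValueError):
            transition_entropy(_seq([1]))


class TestDistanceToHealthy:
    def test_w_median_copies_give_zero(self):
        m = _median_map()
        traj = _traj(np.tile(m.vector("W"), (4, 1)))
        assert distance_to_healthy(traj, m) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_constructed_point(self):
        # healthy medians all equal e1 -> antipodal point has distance 2
        vecs = np.zeros((len(CLASSES), 8))
        vecs[:, 0] = 1.0
        for i, cls in enumerate(CLASSES):
            if cls not in HEALTHY_CLASSES:
                vecs[i] = sample_sphere(1, 8, seed=i)[0]
        m = ClassMedianMap(classes=list(CLASSES), vectors=vecs)
        anti = -np.eye(8)[:1]
        assert distance_to_healthy(_traj(anti), m) == pytest.approx(2.0)

    def test_matches_brute_force(self):
        m = _median_map(seed=7)
        pts = sample_sphere(50, 16, seed=8)
        got = distance_to_healthy(_traj(pts), m)
        ref = np.stack([m.vector(c) / np.linalg.norm(m.vector(c)) for c in HEALTHY_CLASSES])
        expected = np.mean([min(1 - p @ r for r in ref) for p in pts])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_healthy_class(self):
        m = ClassMedianMap(classes=["W", "BS"], vectors=sample_sphere(2, 8, seed=0))
        with pytest.raises(ValueError):
            distance_to_healthy(_traj(sample_sphere(3, 8, seed=1)), m)


def lz76_reference(symbols):
    """Independent exhaustive parser: each phrase is the shortest prefix
    of the remainder absent from the preceding text (self-overlap
    allowed)."""
    s = "".join(chr(48 + int(v)) for v in symbols)
    n, i, c = len(s), 0, 0
    while i < n:
        l = 1
        while i + l <= n and s[i : i + l] in s[: i + l - 1]:
            l += 1
        c += 1
        i += l
    return c


class TestLz76:
    def test_alternation_oracle(self):
        sym = np.array([0, 1] * 500)
        assert lz76_complexity(sym) == lz76_reference(sym)
        assert lz76_complexity(sym) == 3  # phrases: 0 | 1 | 01...01

    def test_constant_minimal(self):
        sym = np.zeros(100, dtype=int)
        assert lz76_complexity(sym) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reference_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for k in (2, 4, 11):
            sym = rng.integers(0, k, size=rng.integers(5, 400))
            assert lz76_complexity(sym) == lz76_reference(sym)


class TestDynamicsFeatures:
    def test_constant_trajectory(self):
        seq = SymbolicSequence.from_labels(["N2"] * 360)  # 1 hour
        f = dynamics_features(seq)
        assert f["transitions_per_hour"] == 0.0
        assert f["n_distinct_symbols"] == 1.0
        assert f["lz76"] == 2.0
        assert f["dwell_mean"] == 3600.0

    def test_occupancies_sum_to_one(self):
        rng = np.random.default_rng(3)
        seq = _seq(rng.integers(0, 11, size=777))
        f = dynamics_features(seq)
        total = sum(f[f"occ_{c}"] for c in CLASSES)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_spatial_features_present_with_trajectory(self):
        m = _median_map()
        pts = sample_sphere(30, 16, seed=9)
        traj = _traj(pts)
        seq = symbolize(traj, m)
        f = dynamics_features(seq, traj=traj, medians=m)
        for key in ("dist_healthy_mean", "path_length", "step_mean", "mean_dist_W"):
            assert key in f
        assert f["path_length"] == pytest.approx(
            sum(1 - pts[i] @ pts[i + 1] for i in range(29)), abs=1e-9
        )


def _cohort_features(n_per_group, bs_good, bs_poor, stick_good, stick_poor, seed,
                     hours=0.5):
    from neuromap.synthetic import CohortSpec, generate_cohort

    def occ(bs):
        rest = (1 - bs) / 10
        v = np.full(11, rest)
        v[CLASSES.index("BS")] = bs
        return v

    spec = CohortSpec(
        n_patients={"good": n_per_group, "poor": n_per_group},
        hours_per_patient=hours,
        occupancy={"good": occ(bs_good), "poor": occ(bs_poor)},
        stickiness={"good": stick_good, "poor": stick_poor},
        seed=seed,
    )
    feats, outcomes, pids, centers = [], [], [], []
    for p in generate_cohort(spec):
        seq = SymbolicSequence.from_labels(p.labels)
        feats.append(dynamics_features(seq))
        outcomes.append(p.outcome)
        pids.append(p.patient_id)
        centers.append(p.center_id)
    return feats, outcomes, pids, centers


class TestOutcomeClassify:
    def test_separable_cohort(self):
        feats, outcomes, pids, _ = _cohort_features(30, 0.02, 0.60, 0.4, 0.7, seed=1)
        res = outcome_classify(feats, outcomes, groups=pids, seed=0)
        assert res.auroc >= 0.95

    def test_null_cohort_near_chance(self):
        feats, outcomes, pids, _ = _cohort_features(50, 0.2, 0.2, 0.5, 0.5, seed=2)
        res = outcome_classify(feats, outcomes, groups=pids, seed=0)
        assert 0.4 <= res.auroc <= 0.6

    def test_center_folds_partition(self):
        feats, outcomes, pids, centers = _cohort_features(15, 0.02, 0.6, 0.4, 0.7, seed=3)
        res = outcome_classify(feats, outcomes, groups=pids, centers=centers,
                               group_by="center", seed=0)
        assert len(res.fold_test_groups) == 5
        for fold in res.fold_test_groups:
            assert len(fold) == 1

    def test_single_outcome_rejected(self):
        feats = [{"a": 1.0}, {"a": 2.0}]
        with pytest.raises(ValueError):
            outcome_classify(feats, ["good", "good"])


class TestLdaSearch:
    def _planted(self, n=200, seed=4):
        rng = np.random.default_rng(seed)
        feats, outcomes = [], []
        for i in range(n):
            poor = i >= n // 2
            f = {f"noise_{j}": float(rng.normal()) for j in range(4)}
            f["time_in_bs"] = float(rng.normal(loc=3.0 if poor else 0.0))
            feats.append(f)
            outcomes.append("poor" if poor else "good")
        return feats, outcomes

    def test_combo_count(self):
        feats, outcomes = self._planted()
        ranked = lda_search(feats, outcomes)
        from math import comb

        assert len(ranked) == comb(5, 2) + comb(5, 3)

    def test_planted_feature_ranks_first(self):
        feats, outcomes = self._planted()
        ranked = lda_search(feats, outcomes)
        # every top combo must contain the only informative feature
        for combo, _auroc in ranked[:5]:
            assert "time_in_bs" in combo

    def test_pure_noise_near_chance(self):
        rng = np.random.default_rng(5)
        feats = [{f"n{j}": float(rng.normal()) for j in range(5)} for _ in range(200)]
        outcomes = ["poor" if i % 2 else "good" for i in range(200)]
        ranked = lda_search(feats, outcomes)
        assert 0.4 <= ranked[0][1] <= 0.65


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        feats = [{"time_in_healthy": 0.5, "time_in_iiic": 0.3, "time_in_bs": 0.2}] * 8
        outcomes = ["good"] * 4 + ["poor"] * 4
        p = group_occupancy_compare(feats, outcomes)
        assert all(v > 0.9 for v in p.values())

    def test_u_statistic_matches_enumeration(self):
        """6-vs-6 toy sample: U equals the brute-force pair count."""
        from scipy.stats import mannwhitneyu

        a = np.array([0.1, 0.5, 0.3, 0.9, 0.2, 0.7])
        b = np.array([0.4, 0.6, 0.8, 0.35, 0.95, 0.35])
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert mannwhitneyu(a, b).statistic == pytest.approx(u_brute)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        feats, outcomes = [], []
        for i in range(100):
            poor = i >= 50
            bs = rng.uniform(0.4, 0.8) if poor else rng.uniform(0.0, 0.2)
            feats.append({"time_in_healthy": 1 - bs, "time_in_iiic": 0.0, "time_in_bs": bs})
            outcomes.append("poor" if poor else "good")
        p = group_occupancy_compare(feats, outcomes)
        assert p["time_in_bs"] < 0.01
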