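"""kNN classification, cross-validation, pruning, and evaluation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flygroom.behaviors import GROOMING, LOCOMOTION, REST
from flygroom.classify import (TrainingSet, classify, cross_validate,
                               evaluate, fit_knn, prune_labels)


def brute_force_neighbors(train, queries, k):
    """Independent exhaustive k-nearest-neighbor search (tie -> lower index)."""
    out = []
    for q in queries:
        d = np.sqrt(((train - q) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(len(train)), d))
        out.append(order[:k])
    return np.array(out)


def brute_force_prune(raw, window, min_grooming):
    """Enumerate every window to decide which grooming frames survive."""
    raw = np.asarray(raw, dtype=object)
    n = len(raw)
    out = raw.copy()
    is_g = raw == GROOMING
    if n < window:
        if is_g.sum() < min_grooming:
            out[is_g] = LOCOMOTION
        return out
    keep = np.zeros(n, dtype=bool)
    for s in range(n - window + 1):
        if is_g[s:s + window].sum() >= min_grooming:
            keep[s:s + window] = True
    out[is_g & ~keep] = LOCOMOTION
    return out


def cluster_training(seed=0, n=200, spread=0.02):
    rng = np.random.default_rng(seed)
    centers = {GROOMING: (0.5, 0.1, 0.0), LOCOMOTION: (0.6, 0.4, 0.12),
               REST: (0.0, 0.0, 0.0)}
    samples, labels = [], []
    for label, c in centers.items():
        samples.append(rng.normal(c, spread, size=(n, 3)))
        labels += [label] * n
    return TrainingSet(np.abs(np.vstack(samples)), np.array(labels, object))


class TestKnnModel:
    def test_k1_query_on_training_point_returns_its_label(self):
        ts = cluster_training()
        model = fit_knn(ts, k=1)
        assert classify(model, ts.samples[:5])[0] == ts.labels[0]

    def test_k_exceeding_sample_count_rejected(self):
        ts = cluster_training(n=3)
        with pytest.raises(ValueError):
            fit_knn(ts, k=100)

    def test_duplicate_points_tie_resolved_to_lowest_index(self):
        samples = np.zeros((4, 3))
        labels = np.array([REST, GROOMING, GROOMING, GROOMING], object)
        model = fit_knn(TrainingSet(samples, labels), k=1)
        _, idx = model.query(np.zeros((1, 3)), k=1)
        assert idx[0, 0] == 0
        assert classify(model, np.zeros((1, 3)))[0] == REST

    def test_tree_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(42)
        train = rng.uniform(0, 1, size=(500, 3))
        labels = np.array([REST] * 500, object)
        model = fit_knn(TrainingSet(train, labels), k=10)
        queries = rng.uniform(0, 1, size=(200, 3))
        _, tree_idx = model.query(queries)
        brute_idx = brute_force_neighbors(train, queries, 10)
        assert np.array_equal(tree_idx, brute_idx)

    def test_vote_tie_broken_by_nearest_neighbor(self):
        # 5 grooming slightly farther, 5 locomotion with the closest point
        samples = np.vstack([np.full((5, 3), 0.20), np.full((5, 3), 0.18)])
        labels = np.array([GROOMING] * 5 + [LOCOMOTION] * 5, object)
        model = fit_knn(TrainingSet(samples, labels), k=10)
        assert classify(model, [[0.17, 0.17, 0.17]])[0] == LOCOMOTION


class TestCrossValidate:
    def test_separable_clusters_are_perfect_for_small_k(self):
        ts = cluster_training(n=60)
        report = cross_validate(ts, k_values=range(1, 6), folds=5, seed=0)
        assert all(acc == 1.0 for acc in report.values())

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(1)
        samples = rng.uniform(0, 1, size=(300, 3))
        labels = np.array([GROOMING, LOCOMOTION, REST] * 100, object)
        report = cross_validate(TrainingSet(samples, labels),
                                k_values=[10], folds=5, seed=0)
        assert abs(report[10] - 1 / 3) < 0.12

    def test_same_seed_reproduces_curves(self):
        ts = cluster_training(n=40, spread=0.3)
        a = cross_validate(ts, k_values=range(1, 8), folds=4, seed=3)
        b = cross_validate(ts, k_values=range(1, 8), folds=4, seed=3)
        assert a == b


G, L, R = GROOMING, LOCOMOTION, REST


class TestPruneLabels:
    def test_fifteen_consecutive_grooming_retained(self):
        raw = np.array([G] * 15, object)
        assert (prune_labels(raw) == G).all()

    def test_isolated_burst_relabeled_locomotion(self):
        raw = np.array([L] * 30 + [G] * 5 + [L] * 30, object)
        pruned = prune_labels(raw)
        assert not (pruned == G).any()
        assert (pruned[30:35] == L).all()

    def test_twelve_of_fifteen_retained(self):
        raw = np.array([G] * 6 + [L, G, L, G, L] + [G] * 4, object)
        assert len(raw) == 15 and (raw == G).sum() == 12
        pruned = prune_labels(raw)
        assert ((pruned == G) == (raw == G)).all()

    def test_non_grooming_labels_never_change(self):
        raw = np.array([R, L] * 40, object)
        assert (prune_labels(raw) == raw).all()

    @given(st.lists(st.sampled_from([G, L, R]), min_size=0, max_size=200),
           st.integers(1, 20), st.integers(1, 20))
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_enumeration(self, labels, window, min_g):
        if min_g > window:
            window, min_g = min_g, window
        raw = np.array(labels, object)
        assert np.array_equal(prune_labels(raw, window, min_g),
                              brute_force_prune(raw, window, min_g))

    @given(st.lists(st.sampled_from([G, L, R]), min_size=20, max_size=120))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_monotone_in_min_grooming(self, labels):
        raw = np.array(labels, object)
        once = prune_labels(raw, 15, 10)
        assert np.array_equal(prune_labels(once, 15, 10), once)
        stricter = prune_labels(raw, 15, 12)
        assert set(np.flatnonzero(stricter == G)) <= \
            set(np.flatnonzero(once == G))


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = np.array([G, G, L, R], object)
        assert evaluate(truth, truth) == (1.0, 1.0)

    def test_no_predicted_grooming(self):
        pred = np.array([L, L, R], object)
        truth = np.array([G, L, R], object)
        precision, recall = evaluate(pred, truth)
        assert np.isnan(precision)
        assert recall == 0.0

    def test_hand_built_confusion_table(self):
        # 3 TP, 1 FP, 2 FN in a 10-frame stream
        truth = np.array([G, G, G, G, G, L, L, L, R, R], object)
        pred = np.array([G, G, G, L, L, G, L, L, R, R], object)
        precision, recall = evaluate(pred, truth)
        assert precision == pytest.approx(0.75)
        assert recall == pytest.approx(0.6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([G], object), np.array([G, L], object))
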