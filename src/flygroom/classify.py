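"""k-nearest-neighbors behavior classification and temporal pruning.

Feature vectors live in the three-dimensional (nPM, nCM, nCD) space.
Each unlabeled frame is assigned the most frequent label among its k
nearest training samples (Euclidean distance, k-d tree search, k = 10).
Because a two-frame feature cannot distinguish grooming from brief
grooming-like movements such as stretching, raw grooming labels are
pruned with a sliding 15-frame window: a grooming frame is kept only if
it lies in at least one window containing 12 or more grooming frames;
otherwise it is relabeled as locomotion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KDTree

from .behaviors import CLASSIFIER_CLASSES, GROOMING, LOCOMOTION

DEFAULT_K = 10
DEFAULT_PRUNE_WINDOW = 15
DEFAULT_MIN_GROOMING = 12


@dataclass
class TrainingSet:
    """Labeled feature vectors for classifier training."""

    samples: np.ndarray  # (n, 3) float array of (nPM, nCM, nCD)
    labels: np.ndarray   # (n,) array of class names
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels lengths differ")
        bad = set(self.labels) - set(CLASSIFIER_CLASSES)
        if bad:
            raise ValueError(f"labels outside the three-class alphabet: {bad}")


@dataclass
class KnnModel:
    """Fitted kNN classifier: training points, labels, and a k-d tree."""

    training: TrainingSet
    k: int = DEFAULT_K
    _tree: KDTree = field(init=False, repr=False)
    _codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.training.samples) == 0:
            raise ValueError("training set is empty")
        if self.k > len(self.training.samples):
            raise ValueError("k exceeds the number of training samples")
        self._tree = KDTree(self.training.samples)
        class_index = {c: i for i, c in enumerate(CLASSIFIER_CLASSES)}
        self._codes = np.array([class_index[l] for l in self.training.labels])

    def query(self, points: np.ndarray, k: int | None = None):
        """Distances and training-sample indices of the k nearest neighbors.

        Neighbor lists are identical to exhaustive search; exact ties in
        distance are resolved toward the lower sample index.
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        dist, idx = self._tree.query(points, k=k or self.k)
        # KDTree breaks exact distance ties arbitrarily; enforce the
        # lowest-sample-index contract with a stable re-sort per query.
        order = np.lexsort((idx, dist), axis=1)
        return np.take_along_axis(dist, order, axis=1), \
            np.take_along_axis(idx, order, axis=1)


def fit_knn(training: TrainingSet, k: int = DEFAULT_K) -> KnnModel:
    """Build the k-d-tree-backed kNN model (k = 10 by default)."""
    return KnnModel(training=training, k=k)


def classify(model: KnnModel, features: np.ndarray) -> np.ndarray:
    """Majority vote among the k nearest neighbors of each feature vector.

    Vote ties are broken by the label of the single nearest neighbor if
    it belongs to a tied class, then by the fixed class order
    grooming < locomotion < rest.
    """
    features = np.asarray(features, dtype=float).reshape(-1, 3)
    _, idx = model.query(features)
    return _vote(model._codes[idx])


def cross_validate(training: TrainingSet, k_values=range(1, 51),
                   folds: int = 10, seed: int = 0) -> dict[int, float]:
    """Stratified k-fold accuracy of the classifier for each k.

    Returns mean held-out accuracy per k; used to confirm the default
    k = 10 balances accuracy against query cost.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, class_counts = np.unique(training.labels.astype(str), return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"a class has only {class_counts.min()} samples; "
            f"use at most that many folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    k_values = list(k_values)
    per_fold = {k: [] for k in k_values}
    y = training.labels.astype(str)
    for train_idx, test_idx in skf.split(training.samples, y):
        sub = TrainingSet(training.samples[train_idx], training.labels[train_idx])
        max_k = max(k_values)
        if max_k > len(train_idx):
            raise ValueError("k exceeds fold training size")
        model = fit_knn(sub, k=max_k)
        _, idx = model.query(training.samples[test_idx], k=max_k)
        neighbor_codes = model._codes[idx]
        truth = training.labels[test_idx]
        for k in k_values:
            sub_model_codes = neighbor_codes[:, :k]
            pred = _vote(sub_model_codes)
            per_fold[k].append(float(np.mean(pred == truth)))
    return {k: float(np.mean(v)) for k, v in per_fold.items()}


def _vote(neighbor_codes: np.ndarray) -> np.ndarray:
    out = np.empty(len(neighbor_codes), dtype=object)
    n_classes = len(CLASSIFIER_CLASSES)
    counts = np.stack([np.sum(neighbor_codes == c, axis=1)
                       for c in range(n_classes)], axis=1)
    top = counts.max(axis=1)
    for i in range(len(neighbor_codes)):
        tied = np.nonzero(counts[i] == top[i])[0]
        if len(tied) == 1:
            code = tied[0]
        elif neighbor_codes[i, 0] in tied:
            code = int(neighbor_codes[i, 0])
        else:
            code = int(tied.min())
        out[i] = CLASSIFIER_CLASSES[code]
    return out


def prune_labels(raw: np.ndarray, window: int = DEFAULT_PRUNE_WINDOW,
                 min_grooming: int = DEFAULT_MIN_GROOMING) -> np.ndarray:
    """Apply the 12/15 sliding-window grooming filter.

    A raw grooming frame keeps its label iff it lies inside at least one
    contiguous window of ``window`` frames containing at least
    ``min_grooming`` raw grooming labels; all other grooming frames are
    relabeled as locomotion.  Non-grooming labels pass through
    unchanged.  A stream shorter than ``window`` is treated as a single
    window of its own length.
    """
    if not (window >= min_grooming >= 1):
        raise ValueError("require window >= min_grooming >= 1")
    raw = np.asarray(raw, dtype=object)
    n = len(raw)
    is_groom = (raw == GROOMING)
    out = raw.copy()
    if n == 0:
        return out
    if n < window:
        if int(is_groom.sum()) < min_grooming:
            out[is_groom] = LOCOMOTION
        return out
    counts = np.convolve(is_groom.astype(int), np.ones(window, dtype=int),
                         mode="valid")  # counts[s] = grooming in [s, s+window)
    passing = counts >= min_grooming
    keep = np.zeros(n, dtype=bool)
    for s in np.nonzero(passing)[0]:
        keep[s:s + window] = True
    relabel = is_groom & ~keep
    out[relabel] = LOCOMOTION
    return out


def evaluate(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Frame-level grooming accuracy (precision) and sensitivity (recall).

    Accuracy = correct grooming labels / all predicted grooming labels;
    sensitivity = identified grooming / all true grooming frames.  A
    zero denominator yields NaN (not applicable).
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    pred_g = pred == GROOMING
    true_g = truth == GROOMING
    tp = int(np.sum(pred_g & true_g))
    precision = tp / pred_g.sum() if pred_g.sum() else float("nan")
    recall = tp / true_g.sum() if true_g.sum() else float("nan")
    return float(precision), float(recall)
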