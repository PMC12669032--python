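"""Species-specific antibacterial-activity classification.

Predicts, per bacterial species, whether a compound inhibits growth, from
molecular feature vectors (a descriptor block plus an optional 768-column
learned-embedding block). Hit labels are heavily imbalanced, so the
pipeline uses stratified 8:2 train/test splits repeated 20 times, a random
forest (500 trees, sqrt feature subsampling) predicting probabilities,
classification by thresholding at the training set's hit frequency, and the
imbalance-appropriate metrics balanced accuracy (mean of sensitivity and
specificity) and average precision (stepwise area under the
precision-recall curve). Shuffled-label refits provide the chance-level
null for both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "select_species",
    "stratified_splits",
    "fit_predict_rf",
    "threshold_at_prevalence",
    "balanced_accuracy",
    "average_precision",
    "shuffled_label_null",
    "ActivityClassifier",
    "ActivityCVResults",
]


def select_species(
    hit_counts: dict[str, tuple[int, int]], min_hits: int = 20
) -> list[str]:
    """Species with strictly more than ``min_hits`` hits in both datasets."""
    return sorted(
        s for s, (a, b) in hit_counts.items() if a > min_hits and b > min_hits
    )


def stratified_splits(
    labels, test_fraction: float = 0.2, n_splits: int = 20, seed=0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified shuffle splits preserving class frequencies.

    Each split holds out ~``test_fraction`` of each class (rounded);
    train and test are disjoint and exhaustive; deterministic under seed.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 members for stratification")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=int(seed)
    )
    return [(train, test) for train, test in splitter.split(np.zeros_like(y), y)]


def fit_predict_rf(
    train_features,
    train_labels,
    test_features,
    n_trees: int = 500,
    max_features: str = "sqrt",
    seed=0,
) -> np.ndarray:
    """Random-forest probability of the positive class for each test compound."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    Xt = np.asarray(test_features, dtype=float)
    if X.shape[1] != Xt.shape[1]:
        raise ValueError("train/test feature count mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        max_depth=None,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    pos = list(clf.classes_).index(1)
    return clf.predict_proba(Xt)[:, pos]


def threshold_at_prevalence(probabilities, train_hit_frequency: float) -> np.ndarray:
    """Classify positive where probability >= the training hit frequency.

    Thresholding at the prevalence rather than 0.5 recovers sensitivity on
    imbalanced data; the comparison is >= so a probability exactly equal to
    the prevalence is called positive.
    """
    p = np.asarray(probabilities, dtype=float)
    return (p >= train_hit_frequency).astype(int)


def balanced_accuracy(truth, predictions) -> float:
    """(sensitivity + specificity) / 2; requires both classes in truth."""
    y = np.asarray(truth, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    pos, neg = (y == 1), (y == 0)
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in truth")
    sens = (yhat[pos] == 1).mean()
    spec = (yhat[neg] == 0).mean()
    return float((sens + spec) / 2.0)


def average_precision(truth, probabilities) -> float:
    """Stepwise area under the precision-recall curve.

    AP = sum_k (R_k - R_{k-1}) * P_k over the score-ranked list, with tied
    scores processed as one block (precision and recall evaluated at block
    boundaries only).
    """
    y = np.asarray(truth, dtype=int)
    scores = np.asarray(probabilities, dtype=float)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("need >= 1 positive in truth")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    ap = 0.0
    tp = 0
    n_seen = 0
    prev_recall = 0.0
    i = 0
    n = len(y_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int((y_sorted[i:j] == 1).sum())
        n_seen += j - i
        recall = tp / n_pos
        precision = tp / n_seen
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


@dataclass(frozen=True)
class CVMetrics:
    """Per-split evaluation metrics."""

    split_id: int
    balanced_accuracy: float
    average_precision: float
    tp: int
    fp: int
    tn: int
    fn: int


def _evaluate_split(
    X: np.ndarray, y: np.ndarray, train: np.ndarray, test: np.ndarray,
    split_id: int, n_trees: int, seed: int,
) -> CVMetrics:
    probs = fit_predict_rf(X[train], y[train], X[test], n_trees=n_trees, seed=seed)
    prevalence = float(y[train].mean())
    preds = threshold_at_prevalence(probs, prevalence)
    yt = y[test]
    tp = int(((preds == 1) & (yt == 1)).sum())
    fp = int(((preds == 1) & (yt == 0)).sum())
    tn = int(((preds == 0) & (yt == 0)).sum())
    fn = int(((preds == 0) & (yt == 1)).sum())
    return CVMetrics(
        split_id=split_id,
        balanced_accuracy=balanced_accuracy(yt, preds),
        average_precision=average_precision(yt, probs),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def shuffled_label_null(
    features,
    labels,
    n_shuffles: int = 20,
    n_splits_per_shuffle: int = 2,
    n_trees: int = 500,
    seed=0,
) -> pd.DataFrame:
    """Chance-level metric distribution from label-permuted refits.

    The full split/fit/threshold/score pipeline is repeated on label-
    shuffled copies of the dataset; returns one row per (shuffle, split).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_shuffles):
        y_shuf = rng.permutation(y)
        splits = stratified_splits(
            y_shuf, n_splits=n_splits_per_shuffle, seed=int(rng.integers(2**31 - 1))
        )
        for i, (train, test) in enumerate(splits):
            m = _evaluate_split(
                X, y_shuf, train, test, i, n_trees, seed=int(rng.integers(2**31 - 1))
            )
            rows.append(
                {
                    "shuffle": k,
                    "split_id": i,
                    "balanced_accuracy": m.balanced_accuracy,
                    "average_precision": m.average_precision,
                }
            )
    return pd.DataFrame(rows)


class ActivityClassifier:
    """Model predicting per-species antibacterial activity from features.

    Parameters
    ----------
    features
        compound x feature DataFrame (descriptor block, optional embedding
        block); no missing values.
    labels
        compound x species DataFrame of binary inhibition labels aligned
        with ``features``.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.DataFrame,
                 descriptor_prefix: str = "bit_"):
        if not features.index.equals(labels.index):
            raise ValueError("features and labels must share the compound index")
        if features.isna().any().any() or labels.isna().any().any():
            raise ValueError("no missing values allowed after assembly")
        self.features = features
        self.labels = labels
        self.descriptor_prefix = descriptor_prefix

    def _feature_matrix(self, descriptor_only: bool) -> pd.DataFrame:
        if not descriptor_only:
            return self.features
        cols = [c for c in self.features.columns if c.startswith(self.descriptor_prefix)]
        if not cols:
            raise ValueError(
                f"no descriptor columns with prefix {self.descriptor_prefix!r}"
            )
        return self.features[cols]

    def fit_cv(
        self,
        species: str,
        n_splits: int = 20,
        test_fraction: float = 0.2,
        n_trees: int = 500,
        seed=0,
        descriptor_only: bool = False,
    ) -> "ActivityCVResults":
        """Cross-validated evaluation for one species.

        ``descriptor_only=True`` restricts training to the descriptor block
        (columns named with ``descriptor_prefix``), excluding the learned
        embedding block.
        """
        y = self.labels[species].to_numpy(dtype=int)
        features = self._feature_matrix(descriptor_only)
        X = features.to_numpy(dtype=float)
        splits = stratified_splits(y, test_fraction, n_splits, seed)
        metrics = [
            _evaluate_split(X, y, train, test, i, n_trees, seed=int(seed) + i + 1)
            for i, (train, test) in enumerate(splits)
        ]
        return ActivityCVResults(self, species, metrics, n_trees, int(seed), features)

    def feature_importances(
        self, species: str, n_trees: int = 500, seed=0
    ) -> pd.Series:
        """Impurity-based importances from a forest fit on the full dataset."""
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=int(seed), n_jobs=1
        )
        clf.fit(self.features.to_numpy(dtype=float), self.labels[species].to_numpy(dtype=int))
        return pd.Series(clf.feature_importances_, index=self.features.columns)


class ActivityCVResults:
    """Cross-validation results for one species."""

    def __init__(self, model: ActivityClassifier, species: str,
                 metrics: list[CVMetrics], n_trees: int, seed: int,
                 features: pd.DataFrame | None = None):
        self.model = model
        self.species = species
        self.split_metrics = metrics
        self.n_trees = n_trees
        self.seed = seed
        self.features = features if features is not None else model.features

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "split_id": m.split_id,
                    "balanced_accuracy": m.balanced_accuracy,
                    "average_precision": m.average_precision,
                    "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                }
                for m in self.split_metrics
            ]
        )

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([m.balanced_accuracy for m in self.split_metrics]))

    @property
    def mean_average_precision(self) -> float:
        return float(np.mean([m.average_precision for m in self.split_metrics]))

    def null_distribution(self, n_shuffles: int = 20,
                          n_splits_per_shuffle: int = 2) -> pd.DataFrame:
        return shuffled_label_null(
            self.features,
            self.model.labels[self.species],
            n_shuffles=n_shuffles,
            n_splits_per_shuffle=n_splits_per_shuffle,
            n_trees=self.n_trees,
            seed=self.seed,
        )

    def summary(self) -> str:
        lines = [
            f"Activity classifier CV results: {self.species}",
            "=" * 44,
            f"splits:                 {len(self.split_metrics)}",
            f"prevalence:             {float(self.model.labels[self.species].mean()):.3f}",
            f"mean balanced accuracy: {self.mean_balanced_accuracy:.3f}",
            f"mean average precision: {self.mean_average_precision:.3f}",
        ]
        return "\n".join(lines)
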