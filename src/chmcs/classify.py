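"""Nearest-neighbor classification and accuracy evaluation.

Decisions use the 1-NN classifier under the city-block (L1) distance: it has
no parameters to tune, so classification accuracy reflects the quality of
the texture representation rather than of the classifier. Accuracy is
reported as the percentage of well-classified query images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = ["EvaluationResult", "knn1_l1", "evaluate_split", "repeated_kfold"]


@dataclass
class EvaluationResult:
    """Accuracy of a 1-NN/L1 evaluation with its bookkeeping."""

    accuracy: float  # percent in [0, 100]
    n_test: int
    confusion: dict = field(default_factory=dict)  # (true, predicted) -> count
    per_fold: list = field(default_factory=list)
    k_folds: int | None = None
    repetitions: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "confusion": {f"{t}->{p}": c for (t, p), c in self.confusion.items()},
            "per_fold": list(self.per_fold),
            "k_folds": self.k_folds,
            "repetitions": self.repetitions,
            "seed": self.seed,
        }


def knn1_l1(train_X: np.ndarray, train_y: np.ndarray, query):
    """Label(s) of the nearest training sample(s) under the L1 distance.

    Distance ties resolve to the smallest training-row index. A single query
    vector returns a scalar label; a matrix of queries returns an array.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    if train_X.ndim != 2 or train_X.shape[0] < 1:
        raise ValueError("a non-empty 2-D training matrix is required")
    q = np.asarray(query, dtype=np.float64)
    single = q.ndim == 1
    q2 = q[None, :] if single else q
    if q2.shape[1] != train_X.shape[1]:
        raise ValueError(
            f"query dimensionality {q2.shape[1]} does not match training "
            f"dimensionality {train_X.shape[1]}"
        )
    d = cdist(q2, train_X, metric="cityblock")
    nearest = d.argmin(axis=1)  # argmin returns the first (smallest) index on ties
    labels = train_y[nearest]
    return labels[0] if single else labels


def _accuracy_pct(pred: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean(pred == truth))


def standardize_train_test(train_X: np.ndarray, test_X: np.ndarray):
    """Z-score both sets with training-set mean and standard deviation.

    Constant training columns are left centered only (unit divisor).
    """
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_X - mu) / sd, (test_X - mu) / sd


def evaluate_split(bank, selected_features, standardize: bool = True) -> EvaluationResult:
    """Test accuracy of 1-NN/L1 on the selected columns of a split bank.

    Training rows (``split == 'train'``) are the references; test rows are
    the queries. Features are z-scored with training statistics by default.
    """
    selected = list(selected_features)
    if not selected:
        raise ValueError("at least one selected feature is required")
    if bank.splits is None:
        raise ValueError("the feature bank carries no train/test split")
    train = bank.rows("train")
    test = bank.rows("test")
    if train.n_samples == 0 or test.n_samples == 0:
        raise ValueError("both train and test rows are required")
    tr = train.X[:, selected]
    te = test.X[:, selected]
    if standardize:
        tr, te = standardize_train_test(tr, te)
    pred = knn1_l1(tr, train.labels, te)
    confusion: dict = {}
    for t, p in zip(test.labels, pred):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
    return EvaluationResult(accuracy=_accuracy_pct(pred, test.labels),
                            n_test=test.n_samples, confusion=confusion)


def repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 3,
    repetitions: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> EvaluationResult:
    """Mean validation accuracy of 1-NN/L1 over repeated stratified K folds.

    Each repetition partitions the samples into K stratified validation
    folds; every sample is validated exactly once per repetition. The
    returned accuracy is the mean over the K x repetitions fold accuracies.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than K={k_folds}"
        )
    splitter = RepeatedStratifiedKFold(n_splits=k_folds, n_repeats=repetitions,
                                       random_state=seed)
    fold_accs = []
    for train_idx, val_idx in splitter.split(X, y):
        tr, va = X[train_idx], X[val_idx]
        if standardize:
            tr, va = standardize_train_test(tr, va)
        pred = knn1_l1(tr, y[train_idx], va)
        fold_accs.append(_accuracy_pct(pred, y[val_idx]))
    return EvaluationResult(accuracy=float(np.mean(fold_accs)), n_test=len(y),
                            per_fold=fold_accs, k_folds=k_folds,
                            repetitions=repetitions, seed=seed)
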