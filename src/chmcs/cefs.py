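"""Clustering-based embedded feature selection (CEFS).

CEFS reduces a high-dimensional texture feature bank to a compact subset in
three stages:

1. **Automatic feature clustering.** Features are nodes of a dependency
   graph whose edges link pairs with ``|Pearson rho| > t``; connected
   components of this graph are the clusters, so features connected only
   through intermediaries ("long dependent") also share a cluster. The
   threshold t is not user-set: the grid t in {0.75, 0.80, 0.85, 0.90, 0.95}
   is scanned and the partition maximizing a cluster separability /
   compactness trace criterion wins.

2. **Trace-guided sequential forward selection.** Starting from the empty
   set, the remaining candidate feature maximizing the class-separability
   trace of the augmented subset is added; the entire cluster of the added
   feature is then removed, so no two selected features are ever redundant
   and the candidate pool shrinks quickly.

3. **Embedded dimension choice.** After each addition the mean validation
   accuracy of a 1-NN/L1 classifier over repeated stratified K folds is
   recorded; the retained dimension d_hat is the argmax of this accuracy
   curve.

Both stages reuse the same criterion ``Tr = trace((W + B)^-1 B)``, with
scatter matrices taken in *sample* space for cluster quality (how separated
and compact the feature clusters are) and in *feature* space for class
separability (how separated and compact the classes are).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .classify import repeated_kfold

__all__ = [
    "THRESHOLD_GRID",
    "ClusterPartition",
    "SelectionTrace",
    "pearson",
    "correlation_matrix",
    "dependency_partition",
    "cluster_quality",
    "auto_threshold",
    "class_separability",
    "run_cefs",
]

#: Correlation thresholds scanned by the automatic clustering stage.
THRESHOLD_GRID = (0.75, 0.80, 0.85, 0.90, 0.95)

_RIDGE = 1e-8


@dataclass
class ClusterPartition:
    """Disjoint feature clusters with the chosen correlation threshold."""

    clusters: list[np.ndarray]  # feature-index arrays, disjoint, covering all features
    t_hat: float
    scores: dict[float, float] = field(default_factory=dict)  # threshold -> Tr

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self) -> np.ndarray:
        """Cluster id of every feature index."""
        size = sum(len(c) for c in self.clusters)
        out = np.empty(size, dtype=np.int64)
        for a, members in enumerate(self.clusters):
            out[members] = a
        return out


@dataclass
class SelectionTrace:
    """Result of one CEFS run."""

    selected: list[int]  # ordered original column indices
    trace_values: list[float]  # class-separability Tr after each addition
    r_bar: list[float]  # mean validation accuracy (percent) per dimension
    d_hat: int
    t_hat: float
    n_clusters: int
    dmax: int
    k_folds: int
    repetitions: int
    seed: int
    standardize: bool
    dropped_constant: list[int] = field(default_factory=list)
    feature_names: list[str] | None = None

    @property
    def selected_d_hat(self) -> list[int]:
        """The final compact subset: the first d_hat selected features."""
        return self.selected[: self.d_hat]

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "trace_values": [float(v) for v in self.trace_values],
            "r_bar": [float(v) for v in self.r_bar],
            "d_hat": int(self.d_hat),
            "t_hat": float(self.t_hat),
            "n_clusters": int(self.n_clusters),
            "dmax": int(self.dmax),
            "k_folds": int(self.k_folds),
            "repetitions": int(self.repetitions),
            "seed": int(self.seed),
            "standardize": bool(self.standardize),
            "dropped_constant": [int(i) for i in self.dropped_constant],
            "feature_names": self.feature_names,
        }


def pearson(xk: np.ndarray, xl: np.ndarray) -> float:
    """Pearson linear correlation of two feature vectors."""
    xk = np.asarray(xk, dtype=np.float64)
    xl = np.asarray(xl, dtype=np.float64)
    if xk.shape != xl.shape or xk.ndim != 1 or xk.size < 2:
        raise ValueError("two equal-length vectors with at least 2 samples are required")
    dk = xk - xk.mean()
    dl = xl - xl.mean()
    nk = float(np.sqrt((dk ** 2).sum()))
    nl = float(np.sqrt((dl ** 2).sum()))
    if nk == 0.0 or nl == 0.0:
        raise ValueError("correlation is undefined for a constant feature")
    return float((dk @ dl) / (nk * nl))


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """D x D Pearson correlations of the columns of X (no constant columns)."""
    X = np.asarray(X, dtype=np.float64)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"column {bad} is constant; remove zero-variance features first")
    c = np.corrcoef(X, rowvar=False)
    return np.atleast_2d(c)


def dependency_partition(X: np.ndarray, t: float, corr: np.ndarray | None = None) -> list[np.ndarray]:
    """Connected components of the |rho| > t dependency graph.

    Returns clusters as sorted index arrays, ordered by their smallest member.
    """
    if corr is None:
        corr = correlation_matrix(X)
    adj = np.abs(corr) > t
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [np.flatnonzero(labels == a) for a in range(n_comp)]
    clusters.sort(key=lambda c: int(c[0]))
    return clusters


def _trace_ratio(W: np.ndarray, B: np.ndarray) -> float:
    """trace((W + B)^-1 B) with a relative ridge; pseudo-inverse fallback."""
    T = W + B
    n = T.shape[0]
    ridge = _RIDGE * np.trace(T) / n if np.trace(T) > 0 else _RIDGE
    try:
        sol = np.linalg.solve(T + ridge * np.eye(n), B)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(T) @ B
    return float(np.trace(sol))


def cluster_quality(X: np.ndarray, clusters: list[np.ndarray]) -> float:
    """Separability/compactness trace of a feature partition, in sample space.

    With mu the mean sample vector over all D features and mu_a the mean over
    cluster a, ``B = (1/D) sum_a |Ca| (mu_a - mu)(mu_a - mu)^T`` and
    ``W = (1/D) sum_a sum_{k in Ca} (x_k - mu_a)(x_k - mu_a)^T`` are N x N
    scatter matrices; the score is ``trace((W + B)^-1 B)``.
    """
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    covered = np.concatenate(clusters) if clusters else np.array([], dtype=int)
    if sorted(covered.tolist()) != list(range(d)):
        raise ValueError("clusters must partition the feature indices 0..D-1")
    mu = X.mean(axis=1)  # N-vector
    B = np.zeros((n, n))
    M = np.empty_like(X)
    for members in clusters:
        mu_a = X[:, members].mean(axis=1)
        diff = mu_a - mu
        B += len(members) * np.outer(diff, diff)
        M[:, members] = X[:, members] - mu_a[:, None]
    B /= d
    W = (M @ M.T) / d
    return _trace_ratio(W, B)


def auto_threshold(
    X: np.ndarray,
    grid: tuple[float, ...] = THRESHOLD_GRID,
    corr: np.ndarray | None = None,
) -> ClusterPartition:
    """Scan the threshold grid and keep the partition of maximal quality.

    Ties on the quality score resolve to the *largest* threshold (the finest
    partition among the tied ones).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("at least 2 features are required for clustering")
    if corr is None:
        corr = correlation_matrix(X)
    best = None
    scores: dict[float, float] = {}
    for t in grid:
        clusters = dependency_partition(X, t, corr=corr)
        tr = cluster_quality(X, clusters)
        scores[t] = tr
        if best is None or tr >= best[0] - 1e-12:
            if best is None or tr > best[0] + 1e-12 or t > best[1]:
                best = (tr, t, clusters)
    _, t_hat, clusters = best
    return ClusterPartition(clusters=clusters, t_hat=t_hat, scores=scores)


def class_separability(X_sub: np.ndarray, y: np.ndarray) -> float:
    """Class separability/compactness trace of a candidate feature subspace.

    With m the global mean and m_j the class means (equal class weights),
    ``B = (1/NC) sum_j (m_j - m)(m_j - m)^T`` and
    ``W = (1/N) sum_j sum_{i in j} (x_i - m_j)(x_i - m_j)^T`` are d x d
    scatter matrices; the score is ``trace((W + B)^-1 B)``.
    """
    X_sub = np.asarray(X_sub, dtype=np.float64)
    if X_sub.ndim == 1:
        X_sub = X_sub[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least 2 classes are required")
    n, d = X_sub.shape
    m = X_sub.mean(axis=0)
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for cls in classes:
        rows = X_sub[y == cls]
        mj = rows.mean(axis=0)
        diff = mj - m
        B += np.outer(diff, diff)
        centered = rows - mj
        W += centered.T @ centered
    B /= classes.size
    W /= n
    return _trace_ratio(W, B)


def run_cefs(
    bank,
    dmax: int = 100,
    k_folds: int = 3,
    repetitions: int = 10,
    seed: int = 0,
    standardize: bool = True,
    threshold_grid: tuple[float, ...] = THRESHOLD_GRID,
) -> SelectionTrace:
    """Run the full CEFS procedure on a labeled feature bank.

    Parameters
    ----------
    bank : FeatureBank
        Labeled training data (its split tags, if any, are ignored: pass the
        training rows).
    dmax : int
        Maximum number of selection steps; caps the learning time.
    k_folds, repetitions, seed
        Parameters of the repeated stratified K-fold validation that scores
        each dimension.
    standardize : bool
        Z-score features (training statistics) before correlation, trace and
        1-NN computations. The bank mixes heterogeneous units (entropies,
        ranges, means over different code scales), so this is on by default.

    Returns
    -------
    SelectionTrace
        Ordered selected features (original column indices), per-step trace
        values, the accuracy curve R_bar, and the chosen dimension d_hat.
    """
    if dmax < 1:
        raise ValueError("dmax must be at least 1")
    X_all = np.asarray(bank.X, dtype=np.float64)
    y = np.asarray(bank.labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has fewer than K={k_folds} samples"
        )

    # Zero-variance screen: Pearson correlation is undefined for constants
    # (and some histogram statistics are constant by construction).
    sd = X_all.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    if keep.size < 2:
        raise ValueError("fewer than 2 non-constant features; nothing to select")
    X = X_all[:, keep]
    if standardize:
        X = (X - X[:, :].mean(axis=0)) / X.std(axis=0)

    partition = auto_threshold(X, grid=threshold_grid)
    cluster_id = partition.cluster_of()

    selected_local: list[int] = []
    trace_values: list[float] = []
    r_bar: list[float] = []
    remaining = np.ones(X.shape[1], dtype=bool)
    rng = np.random.default_rng(seed)

    while len(selected_local) < dmax and remaining.any():
        candidates = np.flatnonzero(remaining)
        base = X[:, selected_local]
        best_tr = -np.inf
        best_k = -1
        for k in candidates:
            tr = class_separability(np.column_stack([base, X[:, k]]), y)
            if tr > best_tr + 1e-12:  # ties resolve to the smallest index
                best_tr = tr
                best_k = int(k)
        selected_local.append(best_k)
        trace_values.append(best_tr)
        remaining[partition.clusters[cluster_id[best_k]]] = False
        fold_seed = int(rng.integers(0, 2**31 - 1))
        res = repeated_kfold(X[:, selected_local], y, k_folds=k_folds,
                             repetitions=repetitions, seed=fold_seed)
        r_bar.append(res.accuracy)

    d_hat = int(np.argmax(r_bar)) + 1  # argmax takes the smallest dimension on ties
    selected = [int(keep[j]) for j in selected_local]
    names = None
    if getattr(bank, "provenance", None):
        names = [bank.provenance[j].name for j in selected]
    return SelectionTrace(
        selected=selected,
        trace_values=trace_values,
        r_bar=r_bar,
        d_hat=d_hat,
        t_hat=partition.t_hat,
        n_clusters=partition.n_clusters,
        dmax=dmax,
        k_folds=k_folds,
        repetitions=repetitions,
        seed=seed,
        standardize=standardize,
        dropped_constant=[int(j) for j in dropped],
        feature_names=names,
    )
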