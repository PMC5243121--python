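"""Correlation-based feature subset selection (CFS) and PCA top-k selection.

A subset of k features is scored by Hall's CFS merit

    M = k * rcf / sqrt(k + k (k-1) * rff)

where rcf is the mean absolute feature-to-label correlation and rff the mean
absolute correlation between distinct subset features: subsets of features
that each track the class but not each other score highest.  Correlations are
Pearson (point-biserial against the binary label) on the raw coefficients —
deterministic and binning-free.  Search is forward best-first with a stall
limit, or plain greedy forward selection; ties break toward the lowest
feature index so results are reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureSubset",
    "feature_label_correlations",
    "feature_feature_correlations",
    "cfs_merit",
    "best_first_search",
    "greedy_forward_search",
    "select_top_pcs",
]


@dataclass(frozen=True)
class FeatureSubset:
    """A selected subset of feature columns (0-based) and its CFS merit.

    The 1-based global coefficient number of column ``i`` is ``i + 1``.
    """

    indices: tuple[int, ...]
    merit: float

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")

    @property
    def coefficient_numbers(self) -> tuple[int, ...]:
        """1-based global coefficient indices."""
        return tuple(i + 1 for i in self.indices)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0  # zero-variance feature carries no correlation signal
    return float(np.corrcoef(a, b)[0, 1])


def feature_label_correlations(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Absolute Pearson (point-biserial) correlation of each feature with the label."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    return np.array([abs(_safe_corr(x[:, j], y)) for j in range(x.shape[1])])


def feature_feature_correlations(features: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation matrix between features (zero-variance -> 0)."""
    x = np.asarray(features, dtype=float)
    sd = x.std(axis=0)
    ok = sd > 0
    r = np.zeros((x.shape[1], x.shape[1]))
    if ok.sum() >= 2:
        sub = np.abs(np.corrcoef(x[:, ok], rowvar=False))
        r[np.ix_(ok, ok)] = sub
    r[np.arange(x.shape[1]), np.arange(x.shape[1])] = 1.0
    return r


def _merit(indices: tuple[int, ...], rcf: np.ndarray, rff: np.ndarray) -> float:
    k = len(indices)
    if k == 0:
        raise ValueError("subset must be nonempty")
    mean_rcf = rcf[list(indices)].mean()
    if k == 1:
        return float(mean_rcf)
    sub = rff[np.ix_(indices, indices)]
    mean_rff = (sub.sum() - k) / (k * (k - 1))
    return float(k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff))


def cfs_merit(features: np.ndarray, labels: np.ndarray, indices) -> float:
    """CFS merit of a feature subset (columns are 0-based indices)."""
    idx = tuple(int(i) for i in indices)
    if len(idx) == 0:
        raise ValueError("subset must be nonempty")
    rcf = feature_label_correlations(features, labels)
    rff = feature_feature_correlations(features)
    return _merit(idx, rcf, rff)


def best_first_search(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    stall_limit: int = 5,
    max_expansions: int = 200,
) -> FeatureSubset:
    """Forward best-first search over feature subsets maximizing CFS merit.

    Maintains an open list of scored subsets, repeatedly expands the
    best-scoring unexpanded one by single-feature additions, and stops after
    ``stall_limit`` consecutive expansions that fail to improve the best merit
    found so far.  Deterministic: ties break toward lexicographically smaller
    index tuples.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features to search")
    rcf = feature_label_correlations(x, labels)
    rff = feature_feature_correlations(x)
    n_feat = x.shape[1]

    scored: dict[tuple[int, ...], float] = {}

    def score(idx: tuple[int, ...]) -> float:
        if idx not in scored:
            scored[idx] = _merit(idx, rcf, rff)
        return scored[idx]

    # seed: every singleton
    heap: list[tuple[float, tuple[int, ...]]] = []
    for j in range(n_feat):
        idx = (j,)
        heapq.heappush(heap, (-score(idx), idx))
    best_idx = max(((j,) for j in range(n_feat)), key=lambda t: (score(t), tuple(-i for i in t)))
    best_merit = score(best_idx)
    expanded: set[tuple[int, ...]] = set()
    stall = 0
    n_exp = 0
    while heap and stall < stall_limit and n_exp < max_expansions:
        neg_m, idx = heapq.heappop(heap)
        if idx in expanded:
            continue
        expanded.add(idx)
        n_exp += 1
        improved = False
        for j in range(n_feat):
            if j in idx:
                continue
            child = tuple(sorted(idx + (j,)))
            if child in scored:
                continue
            m = score(child)
            heapq.heappush(heap, (-m, child))
            if m > best_merit + 1e-12:
                best_merit, best_idx = m, child
                improved = True
        stall = 0 if improved else stall + 1
    return FeatureSubset(indices=tuple(sorted(best_idx)), merit=best_merit)


def greedy_forward_search(features: np.ndarray, labels: np.ndarray) -> FeatureSubset:
    """Greedy forward selection: add the best single feature until no gain."""
    x = np.asarray(features, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features to search")
    rcf = feature_label_correlations(x, labels)
    rff = feature_feature_correlations(x)
    n_feat = x.shape[1]
    current: tuple[int, ...] = ()
    current_merit = -np.inf
    while True:
        best_child, best_m = None, current_merit
        for j in range(n_feat):
            if j in current:
                continue
            child = tuple(sorted(current + (j,)))
            m = _merit(child, rcf, rff)
            if m > best_m + 1e-12:
                best_child, best_m = child, m
        if best_child is None:
            break
        current, current_merit = best_child, best_m
    return FeatureSubset(indices=current, merit=float(current_merit))


def select_top_pcs(basis, k: int = 4) -> tuple[int, ...]:
    """First ``k`` principal components (1-based), the largest-eigenvalue ones."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > basis.n_components:
        raise ValueError("k exceeds the number of components")
    return tuple(range(1, k + 1))
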