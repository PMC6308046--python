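"""Feature ranking and selection: ReliefF and correlation-based selection (CFS).

Both selectors are deterministic: ReliefF iterates every instance in index
order (no subsampling) and ties in weights are broken by the caller-supplied
feature order; the CFS search is a greedy forward best-first search on the
merit criterion with a fixed stall limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureRanking:
    """Ordered selection result: (feature, score) pairs, best first."""

    selector_name: str
    k: int
    ranking: list[tuple[str, float]] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.ranking]

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y = (y == "case").astype(int)
    return y.astype(int)


def relieff_weights(
    X: pd.DataFrame | np.ndarray,
    y,
    n_neighbors: int = 10,
    k: int | None = None,
) -> FeatureRanking:
    """Classic ReliefF feature weights for a binary class.

    Features are min-max scaled internally.  For every instance the
    ``n_neighbors`` nearest same-class (hits) and other-class (misses)
    instances are found by Euclidean distance; each feature's weight
    accumulates miss differences and loses hit differences, normalised by
    instances x neighbours.  A feature that separates the classes gains
    weight; a constant feature scores exactly 0.
    """
    M, names = _as_matrix(X)
    y = _binary_labels(y)
    n, p = M.shape
    if n < 2:
        raise ValueError("need at least 2 instances")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 instances")

    lo, hi = M.min(axis=0), M.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    S = (M - lo) / span

    # pairwise distances once; argsort columns give deterministic neighbours
    diff = S[:, None, :] - S[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)

    if min((y == cls).sum() for cls in np.unique(y)) < n_neighbors + 1:
        warnings.warn("class smaller than n_neighbors+1; neighbour count reduced")

    weights = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero((y == y[i]))
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        k_hit = min(n_neighbors, len(same))
        k_miss = min(n_neighbors, len(other))
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_miss]]
        if k_hit:
            weights -= np.abs(S[hits] - S[i]).sum(axis=0) / (n * k_hit)
        if k_miss:
            weights += np.abs(S[misses] - S[i]).sum(axis=0) / (n * k_miss)

    order = sorted(range(p), key=lambda j: (-weights[j], j))  # ties: input order
    ranking = [(names[j], float(weights[j])) for j in order]
    if k is not None:
        ranking = ranking[:k]
    return FeatureRanking("relieff", k if k is not None else p, ranking)


def cfs_merit(subset: list[str], X: pd.DataFrame, y) -> float:
    """CFS merit of a feature subset: k r_cf / sqrt(k + k(k-1) r_ff).

    r_cf is the mean absolute Pearson correlation of subset features with
    the 0/1 class, r_ff the mean absolute pairwise correlation within the
    subset.  High merit means features individually predictive yet mutually
    non-redundant.  Zero-variance features contribute zero correlations.
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    M = X[list(subset)].to_numpy(dtype=float)
    yv = _binary_labels(y).astype(float)
    k = M.shape[1]
    r_cf = np.array([_abs_pearson(M[:, j], yv) for j in range(k)]).mean()
    if k == 1:
        return float(r_cf)
    r_ffs = [
        _abs_pearson(M[:, i], M[:, j]) for i in range(k) for j in range(i + 1, k)
    ]
    r_ff = float(np.mean(r_ffs))
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def cfs_select(
    X: pd.DataFrame, y, max_k: int = 10, stall_limit: int = 5
) -> FeatureRanking:
    """Greedy forward best-first subset search on CFS merit.

    At each step the single feature whose addition yields the highest merit
    is admitted; the search continues through up to ``stall_limit``
    non-improving expansions and returns the best subset seen, ranked by
    admission order and truncated to ``max_k``.
    """
    names = list(X.columns)
    if not names:
        raise ValueError("need at least one feature")
    selected: list[tuple[str, float]] = []
    best_len = 0
    best_merit = -np.inf
    stall = 0
    remaining = list(names)
    while remaining and stall < stall_limit and len(selected) < max_k + stall_limit:
        merits = [
            (cfs_merit([s for s, _ in selected] + [f], X, y), -names.index(f), f)
            for f in remaining
        ]
        merit, _, feat = max(merits)
        selected.append((feat, float(merit)))
        remaining.remove(feat)
        if merit > best_merit:
            best_merit = merit
            best_len = len(selected)
            stall = 0
        else:
            stall += 1
    chosen = selected[:best_len][:max_k]
    return FeatureRanking("cfs", max_k, chosen)
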