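"""Synthetic minority oversampling (SMOTE) for imbalanced case-control tables.

New minority instances are interpolations between a randomly chosen
minority example and one of its k nearest minority-class neighbours.  The
interpolation point is drawn independently *per feature* (a literal reading
of the procedure used here; canonical SMOTE draws one point per instance —
switchable via ``per_feature_u``).  Only the training split should ever be
augmented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SmoteParams:
    """k_neighbors: neighbours considered per seed example; target_ratio:
    desired minority/majority count ratio after augmentation."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0
    per_feature_u: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must lie in (0, 1]")


def smote_augment(
    X: pd.DataFrame, y: pd.Series | np.ndarray, params: SmoteParams | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Oversample the minority class up to ``target_ratio`` times the majority.

    Original rows are returned unmodified (majority untouched); synthetic
    rows carry the minority label and fresh subject ids.  Neighbour search
    uses Euclidean distance on min-max scaled features (scaling affects the
    distance only, never the synthesised values).  Bit-identical under a
    fixed seed.
    """
    if params is None:
        params = SmoteParams()
    y = pd.Series(np.asarray(y), index=X.index, name="label")
    if not all(np.issubdtype(dt, np.number) for dt in X.dtypes):
        raise ValueError("all features must be numeric")
    counts = y.value_counts()
    if len(counts) != 2:
        raise ValueError("exactly two classes required")
    minority_label = counts.index[-1]
    majority_label = counts.index[0]
    n_min, n_maj = int(counts.iloc[-1]), int(counts.iloc[0])
    if n_min == 0:
        raise ValueError("empty minority class")

    target = int(np.floor(params.target_ratio * n_maj))
    n_new = max(target - n_min, 0)
    if n_new == 0:
        return X.copy(), y.copy()

    k = params.k_neighbors
    if n_min <= k:
        warnings.warn(f"minority class has only {n_min} members; k reduced to {n_min - 1}")
        k = n_min - 1
    if k < 1:
        raise ValueError("minority class too small for SMOTE")

    minority = X[y == minority_label].to_numpy(dtype=float)
    lo, hi = X.min(axis=0).to_numpy(float), X.max(axis=0).to_numpy(float)
    span = hi - lo
    span[span == 0] = 1.0
    scaled = (minority - lo) / span
    d = scaled[:, None, :] - scaled[None, :, :]
    dist = np.sqrt((d**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(params.seed)
    p = minority.shape[1]
    rows = np.empty((n_new, p))
    for s in range(n_new):
        i = int(rng.integers(n_min))
        j = int(neighbours[i, rng.integers(k)])
        u = rng.uniform(size=p) if params.per_feature_u else rng.uniform()
        rows[s] = minority[i] + u * (minority[j] - minority[i])

    synth_index = [f"smote_{s:05d}" for s in range(n_new)]
    X_new = pd.DataFrame(rows, columns=X.columns, index=synth_index)
    y_new = pd.Series([minority_label] * n_new, index=synth_index, name="label")
    return pd.concat([X, X_new]), pd.concat([y, y_new])
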