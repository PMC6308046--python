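"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import numpy as np


def ccc_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's CCC via the correlation form: 2 r sx sy / (sx^2 + sy^2 + d^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x.std()  # population
    sy = y.std()
    if sx == 0 and sy == 0 and x.mean() == y.mean():
        return 1.0
    r = np.corrcoef(x, y)[0, 1] if sx > 0 and sy > 0 else 0.0
    return float(2 * r * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2))


def auroc_pairs_oracle(y_true: np.ndarray, scores: np.ndarray) -> float:
    """All case-control pairs concordance count, ties worth 1/2."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def rln_oracle(levels: np.ndarray, direction: tuple[int, int, int]) -> float:
    """Exhaustive run enumeration for one direction; levels has -1 outside mask."""
    shape = np.array(levels.shape)
    d = np.array(direction)
    starts = [
        tuple(c)
        for c in np.argwhere(np.ones(levels.shape, bool))
        if not ((np.array(c) - d >= 0) & (np.array(c) - d < shape)).all()
    ]
    lengths: list[int] = []
    for start in starts:
        pos = np.array(start)
        cur, cur_len = -1, 0
        while ((pos >= 0) & (pos < shape)).all():
            lev = int(levels[tuple(pos)])
            if lev == cur and lev >= 0:
                cur_len += 1
            else:
                if cur >= 0:
                    lengths.append(cur_len)
                cur, cur_len = lev, (1 if lev >= 0 else 0)
            pos = pos + d
        if cur >= 0:
            lengths.append(cur_len)
    if not lengths:
        return float("nan")
    counts: dict[int, int] = {}
    for ln in lengths:
        counts[ln] = counts.get(ln, 0) + 1
    total = sum(counts.values())
    return sum(c**2 for c in counts.values()) / total


def avg_rln_oracle(image: np.ndarray, mask: np.ndarray, n_levels: int, directions) -> float:
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.full(mask.shape, -1, dtype=int)
    if hi == lo:
        levels[mask] = 0
    else:
        q = np.clip(np.floor((vals - lo) / (hi - lo) * n_levels).astype(int), 0, n_levels - 1)
        levels[mask] = q
    return float(np.mean([rln_oracle(levels, d) for d in directions]))


def relieff_oracle(X: np.ndarray, y: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Literal nested-loop ReliefF on min-max scaled features."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    lo, hi = X.min(0), X.max(0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    S = (X - lo) / span
    w = np.zeros(p)
    for i in range(n):
        dists = np.sqrt(((S - S[i]) ** 2).sum(1))
        same = [j for j in range(n) if j != i and y[j] == y[i]]
        other = [j for j in range(n) if y[j] != y[i]]
        same.sort(key=lambda j: (dists[j], j))
        other.sort(key=lambda j: (dists[j], j))
        hits = same[: min(n_neighbors, len(same))]
        misses = other[: min(n_neighbors, len(other))]
        for f in range(p):
            if hits:
                w[f] -= sum(abs(S[j, f] - S[i, f]) for j in hits) / (n * len(hits))
            if misses:
                w[f] += sum(abs(S[j, f] - S[i, f]) for j in misses) / (n * len(misses))
    return w


def cfs_merit_oracle(M: np.ndarray, yv: np.ndarray) -> float:
    """CFS merit from explicitly assembled correlation averages."""
    k = M.shape[1]
    rcf = []
    for j in range(k):
        sj = M[:, j].std()
        rcf.append(abs(np.corrcoef(M[:, j], yv)[0, 1]) if sj > 0 and yv.std() > 0 else 0.0)
    r_cf = float(np.mean(rcf))
    if k == 1:
        return r_cf
    rff = []
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = M[:, i].std(), M[:, j].std()
            rff.append(abs(np.corrcoef(M[:, i], M[:, j])[0, 1]) if si > 0 and sj > 0 else 0.0)
    r_ff = float(np.mean(rff))
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))
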