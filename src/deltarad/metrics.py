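"""Discrimination and classification metrics with 95% confidence intervals."""

from __future__ import annotations

import numpy as np
from scipy import stats

Z95 = 1.959963984540054


def auroc_mann_whitney(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC as the normalised Mann-Whitney U statistic (ties count 1/2).

    Equals the probability that a uniformly chosen positive scores above a
    uniformly chosen negative, ties broken at random — identical to the
    trapezoidal area under the empirical ROC curve.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_ci_hanley_mcneil(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley–McNeil analytic 95% CI for an AUROC estimate."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    return (max(auc - Z95 * se, 0.0), min(auc + Z95 * se, 1.0))


def auroc_ci_bootstrap(
    y_true: np.ndarray, scores: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for AUROC (stratified resampling)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos))
        ns = rng.choice(neg, size=len(neg))
        yy = np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)])
        aucs[b] = auroc_mann_whitney(yy, np.concatenate([ps, ns]))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return (float(lo), float(hi))


def proportion_ci(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a proportion, clipped to [0, 1]."""
    if n == 0:
        return (float("nan"), float("nan"))
    se = np.sqrt(p * (1.0 - p) / n)
    return (max(p - Z95 * se, 0.0), min(p + Z95 * se, 1.0))
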