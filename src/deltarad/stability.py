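"""Test/retest stability filtering and delta-feature construction.

Two annual screens of the same (mostly unchanged) nodules act as a
test/retest pair: a feature is *stable* when both Lin's concordance
correlation coefficient and the dynamic range across subjects exceed a
threshold (default 0.95, strict inequality, both must pass).  Delta
features are the plain per-subject difference T1 - T0 — the inter-scan
interval is nearly constant across subjects, so no time normalisation is
applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DELTA_PREFIX = "∆ "
#: ASCII alias accepted on input for the delta prefix
DELTA_PREFIX_ASCII = "delta_"

STABILITY_THRESHOLD = 0.95


def concordance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mu_x - mu_y)^2).  Measures agreement
    with the 45-degree line, not just correlation.  Two equal constant
    sequences are perfectly concordant by convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        warnings.warn("both sequences constant and equal; CCC undefined, returning 1")
        return 1.0
    return float(2.0 * sxy / denom)


def dynamic_range(x: np.ndarray, y: np.ndarray) -> float:
    """Repeatability index: 1 - mean |x - y| / pooled range of x and y.

    1 means perfect agreement; 0 means the typical test/retest difference
    is as large as the feature's whole dynamic range.  A feature with zero
    pooled range is constant, hence perfectly repeatable (returned as 1
    with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    pooled = np.concatenate([x, y])
    rng = float(pooled.max() - pooled.min())
    if rng == 0.0:
        warnings.warn("zero pooled range; dynamic range undefined, returning 1")
        return 1.0
    return float(1.0 - np.abs(x - y).mean() / rng)


def _align(table_t0: pd.DataFrame, table_t1: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(table_t0.index) != set(table_t1.index):
        raise ValueError("T0 and T1 tables must cover the same subjects")
    if list(table_t0.columns) != list(table_t1.columns):
        if set(table_t0.columns) != set(table_t1.columns):
            raise ValueError("T0 and T1 tables must share feature columns")
        table_t1 = table_t1[table_t0.columns]
    return table_t0, table_t1.loc[table_t0.index]


def stable_features(
    table_t0: pd.DataFrame,
    table_t1: pd.DataFrame,
    threshold: float = STABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature stability report: ccc, dynamic_range and the stable flag.

    ``stable`` requires *both* statistics strictly above ``threshold``.
    Tables are subjects x features with matching subject indices.
    """
    t0, t1 = _align(table_t0, table_t1)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in t0.columns:
            ccc = concordance_correlation(t0[col].to_numpy(), t1[col].to_numpy())
            dr = dynamic_range(t0[col].to_numpy(), t1[col].to_numpy())
            rows.append(
                {
                    "feature": col,
                    "ccc": ccc,
                    "dynamic_range": dr,
                    "stable": bool(ccc > threshold and dr > threshold),
                }
            )
    return pd.DataFrame(rows).set_index("feature")


def delta_table(table_t0: pd.DataFrame, table_t1: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-feature change T1 - T0, feature names prefixed '∆ '."""
    t0, t1 = _align(table_t0, table_t1)
    delta = t1 - t0
    delta.columns = [DELTA_PREFIX + str(c) for c in delta.columns]
    return delta


def normalize_delta_names(columns: list[str]) -> list[str]:
    """Map the ASCII alias 'delta_' onto the canonical '∆ ' prefix."""
    return [
        DELTA_PREFIX + c[len(DELTA_PREFIX_ASCII):] if c.startswith(DELTA_PREFIX_ASCII) else c
        for c in columns
    ]
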