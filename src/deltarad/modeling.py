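"""Size-stratified case-control classification and evaluation.

The analysis splits nodules by baseline longest diameter into size classes,
trains one classifier per stratum on the training cohort (after feature
selection and optional SMOTE rebalancing) and evaluates on the held-out
test cohort.  Per-stratum confusion matrices are summed and per-stratum
probability lists concatenated to obtain overall (pooled) statistics.

The model *search* mirrors a best-on-test protocol: for every cell
(feature kind x size class) all grid points are evaluated on the test
cohort and the highest test AUROC wins.  That protocol optimistically
biases the winner's estimate — it is reproduced here for fidelity to the
original analysis, not endorsed; every report carries the caveat.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import auroc_ci_hanley_mcneil, auroc_mann_whitney, proportion_ci
from .selection import FeatureRanking, cfs_select, relieff_weights
from .smote import SmoteParams, smote_augment
from .stability import DELTA_PREFIX

logger = logging.getLogger(__name__)

SELECTION_BIAS_NOTE = (
    "Models were selected by highest AUROC on the test cohort; "
    "best-on-test selection optimistically biases performance estimates."
)

CLASSIFIER_ORDER = (
    "decision_tree",
    "rule_list",
    "naive_bayes",
    "svm_rbf",
    "svm_linear",
    "random_forest",
)

SVM_C_GRID = [2.0**e for e in range(-5, 16, 2)]
SVM_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]
# libsvm can fail to converge at large C on inseparable data; cap iterations
SVM_MAX_ITER = 20_000


# ---------------------------------------------------------------------------
# size classes


@dataclass(frozen=True)
class SizeClassScheme:
    """Partition of (0, inf) by baseline longest diameter, lower bound inclusive."""

    name: str
    boundaries: tuple[float, ...]
    class_names: tuple[str, ...]


THREE_CLASS = SizeClassScheme("three_class", (6.0, 16.0), ("small", "intermediate", "large"))
TWO_CLASS = SizeClassScheme("two_class", (6.0,), ("small", "large"))
SCHEMES = {s.name: s for s in (THREE_CLASS, TWO_CLASS)}


def assign_size_class(ld_mm: float, scheme: SizeClassScheme = THREE_CLASS) -> str:
    """Size class of a nodule with baseline longest diameter ``ld_mm``."""
    if ld_mm <= 0:
        raise ValueError("longest diameter must be positive")
    idx = int(np.searchsorted(scheme.boundaries, ld_mm, side="right"))
    return scheme.class_names[idx]


# ---------------------------------------------------------------------------
# model specification and training


@dataclass(frozen=True)
class ModelSpec:
    """One point of the search grid."""

    feature_kind: str = "baseline_plus_delta"  # or baseline_only
    selector: str = "relieff"  # or cfs
    k: int = 5
    classifier: str = "random_forest"
    smote: bool = False
    size_class: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_kind not in ("baseline_only", "baseline_plus_delta"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.selector not in ("relieff", "cfs"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIER_ORDER:
            raise ValueError(f"unknown classifier {self.classifier!r}")


class _SigmoidSVC:
    """SVC scored through a logistic link on its decision function.

    Provides a deterministic predict_proba-style score without the extra
    internal cross-validation of Platt calibration; hyperparameters are
    found by 5-fold grid search on the training set.
    """

    def __init__(self, kernel: str, seed: int):
        self.kernel = kernel
        self.seed = seed
        self.pipe_: Pipeline | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        gammas = SVM_GAMMA_GRID if self.kernel == "rbf" else [1.0]
        n_splits = min(5, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        folds = list(cv.split(X, y))
        # standardise once per fold, reuse across the whole grid
        prepared = []
        for tr, te in folds:
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            prepared.append(((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, y[te]))
        best = (-np.inf, SVM_C_GRID[0], gammas[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in SVM_C_GRID:
                for g in gammas:
                    aucs = []
                    for Xtr, ytr, Xte, yte in prepared:
                        svc = SVC(kernel=self.kernel, C=c, gamma=g, max_iter=SVM_MAX_ITER,
                                  random_state=self.seed)
                        svc.fit(Xtr, ytr)
                        if len(np.unique(yte)) < 2:
                            continue
                        aucs.append(auroc_mann_whitney(yte, svc.decision_function(Xte)))
                    score = float(np.mean(aucs)) if aucs else -np.inf
                    if score > best[0]:
                        best = (score, c, g)
            self.pipe_ = Pipeline(
                [("scale", StandardScaler()),
                 ("svc", SVC(kernel=self.kernel, C=best[1], gamma=best[2],
                             max_iter=SVM_MAX_ITER, random_state=self.seed))]
            )
            self.pipe_.fit(X, y)
        return self

    def predict_proba(self, X):
        df = self.pipe_.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-df))
        return np.column_stack([1.0 - p1, p1])


def _make_classifier(name: str, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "rule_list":
        # pruned decision-list stand-in for a RIPPER-style rule learner
        logger.info("rule_list uses a pruned decision-list (depth-3 entropy tree)")
        return DecisionTreeClassifier(criterion="entropy", max_depth=3, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm_rbf":
        return _SigmoidSVC("rbf", seed)
    if name == "svm_linear":
        return _SigmoidSVC("linear", seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def filter_feature_kind(X: pd.DataFrame, feature_kind: str) -> pd.DataFrame:
    if feature_kind == "baseline_only":
        return X[[c for c in X.columns if not c.startswith(DELTA_PREFIX)]]
    return X


@dataclass
class FittedModel:
    spec: ModelSpec
    features: list[str]
    clf: object
    ranking: FeatureRanking


def train_model(spec: ModelSpec, X: pd.DataFrame, y: pd.Series | np.ndarray) -> FittedModel:
    """Selector -> top-k -> optional SMOTE -> classifier fit, deterministically."""
    y = pd.Series(np.asarray(y), index=X.index)
    yb = (y == "case").astype(int) if y.dtype == object else y.astype(int)
    if yb.nunique() < 2 or yb.value_counts().min() < 2:
        raise ValueError("need at least 2 instances of each class to train")
    Xk = filter_feature_kind(X, spec.feature_kind)

    if spec.selector == "relieff":
        ranking = relieff_weights(Xk, yb.to_numpy(), k=spec.k)
    else:
        ranking = cfs_select(Xk, yb.to_numpy(), max_k=spec.k)
    features = ranking.features[: spec.k]
    Xs = Xk[features]

    if spec.smote:
        Xs, yb = smote_augment(Xs, yb, SmoteParams(seed=spec.seed))

    clf = _make_classifier(spec.classifier, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs.to_numpy(dtype=float), yb.to_numpy())
    return FittedModel(spec=spec, features=features, clf=clf, ranking=ranking)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    """Confusion matrix, probability list and headline metrics with 95% CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    subject_ids: list[str]
    y_true: np.ndarray
    probabilities: np.ndarray
    auroc: float | None
    auroc_ci: tuple[float, float] | None
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    features: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci) if self.auroc_ci else None,
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n": self.n,
            "features": self.features,
        }


def _result_from_scores(
    subject_ids: list[str],
    y_true: np.ndarray,
    probs: np.ndarray,
    features: list[str],
    spec: ModelSpec | None,
) -> EvaluationResult:
    pred = (probs >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    n = len(y_true)
    n_pos, n_neg = int(y_true.sum()), int(n - y_true.sum())
    if n_pos and n_neg:
        auc = auroc_mann_whitney(y_true, probs)
        auc_ci = auroc_ci_hanley_mcneil(auc, n_pos, n_neg)
    else:
        auc, auc_ci = None, None
    accuracy = (tp + tn) / n
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    return EvaluationResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        subject_ids=list(subject_ids), y_true=y_true, probabilities=probs,
        auroc=auc, auroc_ci=auc_ci,
        accuracy=accuracy, accuracy_ci=proportion_ci(accuracy, n),
        sensitivity=sensitivity,
        sensitivity_ci=proportion_ci(sensitivity, n_pos) if n_pos else (float("nan"),) * 2,
        specificity=specificity,
        specificity_ci=proportion_ci(specificity, n_neg) if n_neg else (float("nan"),) * 2,
        features=features, spec=spec,
    )


def evaluate(model: FittedModel, X: pd.DataFrame, y: pd.Series | np.ndarray) -> EvaluationResult:
    """Score a fitted model on a disjoint test table (case = positive class)."""
    y = pd.Series(np.asarray(y), index=X.index)
    y_true = ((y == "case") if y.dtype == object else y.astype(bool)).astype(int).to_numpy()
    probs = np.asarray(model.clf.predict_proba(X[model.features].to_numpy(dtype=float)))[:, 1]
    return _result_from_scores(list(X.index), y_true, probs, model.features, model.spec)


def pool_results(results: list[EvaluationResult]) -> EvaluationResult:
    """Pool disjoint strata: sum confusion matrices, concatenate probabilities.

    Accuracy/sensitivity/specificity are recomputed from the summed matrix
    (micro-averaging); the overall AUROC is computed on the merged
    probability list against the merged labels.
    """
    if not results:
        raise ValueError("nothing to pool")
    all_ids = [sid for r in results for sid in r.subject_ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("strata overlap: a subject appears in more than one result")
    y = np.concatenate([r.y_true for r in results])
    probs = np.concatenate([r.probabilities for r in results])
    pooled = _result_from_scores(all_ids, y, probs, [], None)
    return pooled


# ---------------------------------------------------------------------------
# grid search over model specs


def default_grid(
    feature_kinds=("baseline_only", "baseline_plus_delta"),
    selectors=("relieff", "cfs"),
    ks=(5, 10),
    classifiers=CLASSIFIER_ORDER,
    smote_options=(False, True),
    size_classes=("all",),
    seed: int = 0,
) -> list[ModelSpec]:
    """The full factorial grid of model specifications."""
    return [
        ModelSpec(fk, sel, k, clf, sm, sc, seed)
        for fk in feature_kinds
        for sc in size_classes
        for sel in selectors
        for k in ks
        for clf in classifiers
        for sm in smote_options
    ]


@dataclass
class SearchCell:
    """Winner and leaderboard for one (feature_kind, size_class) cell."""

    feature_kind: str
    size_class: str
    winner: EvaluationResult | None
    leaderboard: list[EvaluationResult]
    note: str = SELECTION_BIAS_NOTE
    skipped_reason: str | None = None


def model_search(
    grid: list[ModelSpec],
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
) -> dict[tuple[str, str], SearchCell]:
    """Evaluate every grid point; keep the best test-AUROC model per cell.

    Ties are broken toward fewer selected features, then by the classifier
    enumeration order.  The full leaderboard is retained for audit.
    """
    if not grid:
        raise ValueError("empty grid")
    overlap = set(X_train.index) & set(X_test.index)
    if overlap:
        raise ValueError(f"train/test subject overlap: {sorted(overlap)[:5]}")
    cells: dict[tuple[str, str], SearchCell] = {}
    by_cell: dict[tuple[str, str], list[ModelSpec]] = {}
    for spec in grid:
        by_cell.setdefault((spec.feature_kind, spec.size_class), []).append(spec)
    for (fk, sc), specs in by_cell.items():
        board: list[EvaluationResult] = []
        for spec in specs:
            try:
                model = train_model(spec, X_train, y_train)
                board.append(evaluate(model, X_test, y_test))
            except ValueError as exc:
                logger.warning("spec %s skipped: %s", spec, exc)
        scored = [r for r in board if r.auroc is not None]
        if not scored:
            cells[(fk, sc)] = SearchCell(fk, sc, None, board,
                                         skipped_reason="no evaluable model in stratum")
            continue
        winner = max(
            scored,
            key=lambda r: (
                r.auroc,
                -len(r.features),
                -CLASSIFIER_ORDER.index(r.spec.classifier),
            ),
        )
        cells[(fk, sc)] = SearchCell(fk, sc, winner, board)
    return cells
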