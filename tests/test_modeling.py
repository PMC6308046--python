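"""Size classes, AUROC, pooling semantics, training and the model search."""

import numpy as np
import pandas as pd
import pytest

from deltarad import (
    THREE_CLASS,
    TWO_CLASS,
    ModelSpec,
    assign_size_class,
    auroc_mann_whitney,
    evaluate,
    model_search,
    pool_results,
    train_model,
)
from deltarad.modeling import _result_from_scores

from oracles import auroc_pairs_oracle


class TestSizeClasses:
    @pytest.mark.parametrize(
        "ld,three,two",
        [(5.9, "small", "small"), (6.0, "intermediate", "large"),
         (15.9, "intermediate", "large"), (16.0, "large", "large"),
         (30.0, "large", "large"), (0.5, "small", "small")],
    )
    def test_boundary_conventions(self, ld, three, two):
        assert assign_size_class(ld, THREE_CLASS) == three
        assert assign_size_class(ld, TWO_CLASS) == two

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_size_class(0.0)


class TestAuroc:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.9, 0.1, 0.1])
        assert auroc_mann_whitney(y, s) == 1.0

    def test_constant_scores_give_half(self):
        y = np.array([1, 0, 1, 0])
        assert auroc_mann_whitney(y, np.full(4, 0.5)) == 0.5

    def test_four_subject_pair_count(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.8, 0.4, 0.6, 0.2])
        assert auroc_mann_whitney(y, s) == 0.75

    def test_matches_all_pairs_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.uniform(size=n), 1)  # coarse: force ties
            ours = auroc_mann_whitney(y, s)
            assert ours == pytest.approx(auroc_pairs_oracle(y, s), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestPooling:
    def _res(self, y, s, ids):
        return _result_from_scores(ids, np.array(y), np.array(s, float), [], None)

    def test_single_stratum_identity(self):
        r = self._res([1, 0, 1, 0], [0.9, 0.2, 0.7, 0.4], list("abcd"))
        pooled = pool_results([r])
        assert pooled.auroc == r.auroc
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (r.tp, r.fp, r.tn, r.fn)

    def test_pooled_auroc_can_drop_below_stratum_aurocs(self):
        # each stratum perfectly separated, but on different score scales
        r1 = self._res([1, 0], [0.6, 0.4], ["a", "b"])
        r2 = self._res([1, 0], [0.3, 0.05], ["c", "d"])
        assert r1.auroc == r2.auroc == 1.0
        pooled = pool_results([r1, r2])
        assert pooled.auroc < 1.0
        assert pooled.auroc == pytest.approx(
            auroc_pairs_oracle(np.array([1, 0, 1, 0]), np.array([0.6, 0.4, 0.3, 0.05]))
        )

    def test_summed_matrix_equals_micro_average_exactly(self):
        rng = np.random.default_rng(1)
        results = []
        all_y, all_s = [], []
        for k in range(3):
            n = 30
            y = rng.integers(0, 2, n)
            y[0], y[1] = 0, 1
            s = rng.uniform(size=n)
            ids = [f"g{k}_{i}" for i in range(n)]
            results.append(self._res(y, s, ids))
            all_y.append(y)
            all_s.append(s)
        pooled = pool_results(results)
        y = np.concatenate(all_y)
        s = np.concatenate(all_s)
        pred = (s >= 0.5).astype(int)
        assert pooled.accuracy == (pred == y).mean()
        assert pooled.sensitivity == pred[y == 1].mean()
        assert pooled.specificity == (1 - pred[y == 0]).mean()
        assert pooled.auroc == pytest.approx(auroc_mann_whitney(y, s), abs=1e-15)
        # instance-weighted mean of stratum accuracies
        weighted = sum(r.accuracy * r.n for r in results) / sum(r.n for r in results)
        assert pooled.accuracy == pytest.approx(weighted, abs=1e-12)

    def test_overlapping_subjects_rejected(self):
        r1 = self._res([1, 0], [0.9, 0.1], ["a", "b"])
        r2 = self._res([1, 0], [0.9, 0.1], ["b", "c"])
        with pytest.raises(ValueError):
            pool_results([r1, r2])


def _separable(n=100, p=8, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.repeat(["control", "case"], n // 2),
                  index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"feat_{j}" for j in range(p // 2)]
                     + [f"∆ feat_{j}" for j in range(p // 2)],
                     index=y.index)
    X.iloc[:, 0] += effect * (y == "case").to_numpy()
    X.iloc[:, p // 2] += effect * (y == "case").to_numpy()
    return X, y


class TestTrainEvaluate:
    @pytest.mark.parametrize("classifier", ["decision_tree", "rule_list", "naive_bayes",
                                            "svm_linear", "random_forest"])
    def test_separable_data_high_training_accuracy(self, classifier):
        X, y = _separable()
        model = train_model(ModelSpec(classifier=classifier, seed=1), X, y)
        res = evaluate(model, X.set_axis([f"t{i}" for i in range(len(X))]), y.set_axis(
            [f"t{i}" for i in range(len(X))]))
        assert res.accuracy >= 0.95

    def test_same_spec_seed_reproducible(self):
        X, y = _separable(seed=2)
        spec = ModelSpec(classifier="random_forest", smote=True, seed=9)
        m1 = train_model(spec, X, y)
        m2 = train_model(spec, X, y)
        assert m1.features == m2.features
        Xt = X.set_axis([f"t{i}" for i in range(len(X))])
        p1 = m1.clf.predict_proba(Xt[m1.features].to_numpy())[:, 1]
        p2 = m2.clf.predict_proba(Xt[m2.features].to_numpy())[:, 1]
        assert np.array_equal(p1, p2)

    def test_baseline_only_excludes_delta_features(self):
        X, y = _separable()
        model = train_model(ModelSpec(feature_kind="baseline_only", k=4, seed=0), X, y)
        assert all(not f.startswith("∆ ") for f in model.features)

    def test_degenerate_training_raises(self):
        X, y = _separable(n=10)
        with pytest.raises(ValueError):
            train_model(ModelSpec(), X, y.map(lambda _: "case"))

    def test_svm_grid_search_runs(self):
        X, y = _separable(n=40)
        model = train_model(ModelSpec(classifier="svm_rbf", k=3, seed=0), X, y)
        Xt = X.set_axis([f"t{i}" for i in range(len(X))])
        probs = model.clf.predict_proba(Xt[model.features].to_numpy())[:, 1]
        assert np.all((probs >= 0) & (probs <= 1))


class TestModelSearch:
    def test_single_spec_grid_returns_it(self):
        Xtr, ytr = _separable(seed=3)
        Xte, yte = _separable(seed=4)
        Xte = Xte.set_axis([f"t{i}" for i in range(len(Xte))])
        yte = yte.set_axis(Xte.index)
        spec = ModelSpec(classifier="naive_bayes", size_class="all")
        cells = model_search([spec], Xtr, ytr, Xte, yte)
        cell = cells[("baseline_plus_delta", "all")]
        assert cell.winner.spec == spec

    def test_dominated_spec_never_wins(self):
        Xtr, ytr = _separable(seed=5)
        Xte, yte = _separable(seed=6)
        Xte = Xte.set_axis([f"t{i}" for i in range(len(Xte))])
        yte = yte.set_axis(Xte.index)
        good = ModelSpec(classifier="naive_bayes")
        base = model_search([good], Xtr, ytr, Xte, yte)[("baseline_plus_delta", "all")]
        # a 1-feature decision stump on noise cannot beat the informative model
        bad = ModelSpec(classifier="decision_tree", selector="relieff", k=1,
                        feature_kind="baseline_plus_delta")
        both = model_search([good, bad], Xtr, ytr, Xte, yte)[("baseline_plus_delta", "all")]
        assert both.winner.auroc >= base.winner.auroc

    def test_train_test_overlap_rejected(self):
        X, y = _separable()
        with pytest.raises(ValueError):
            model_search([ModelSpec()], X, y, X, y)
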