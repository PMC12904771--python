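from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB

from divorph.classify import (
    ENSEMBLE_MODELS,
    ensemble_call,
    ensemble_predict,
    evaluate,
    importance,
    metrics_from_confusion,
    split_train_test,
    train_all,
    tune_and_fit,
)
from oracles import metrics_oracle


def _labeled(n, rng, separation=3.0, n_features=4):
    """Balanced table with the first feature carrying the signal."""
    half = n // 2
    x = rng.normal(0, 1, size=(n, n_features))
    y = np.array([0] * half + [1] * (n - half))
    x[:, 0] += separation * y
    cols = [f"f{i}" for i in range(n_features)]
    t = pd.DataFrame(x, columns=cols)
    t["CLASS"] = y
    return t


class TestSplit:
    def test_75_25_balanced(self, rng):
        t = _labeled(400, rng)
        train, test = split_train_test(t, seed=1)
        assert len(train) == 300 and len(test) == 100
        assert (test["CLASS"] == 1).sum() == 50

    def test_partition(self, rng):
        t = _labeled(100, rng)
        t["query_id"] = [f"q{i}" for i in range(100)]
        train, test = split_train_test(t, seed=2)
        ids = set(train["query_id"]) | set(test["query_id"])
        assert ids == set(t["query_id"])
        assert not (set(train["query_id"]) & set(test["query_id"]))

    def test_stratification_within_one_row(self, rng):
        for n0, n1 in [(11, 9), (13, 14), (21, 10)]:
            x = rng.normal(size=(n0 + n1, 2))
            t = pd.DataFrame(x, columns=["a", "b"])
            t["CLASS"] = [0] * n0 + [1] * n1
            train, test = split_train_test(t, seed=3)
            for cls, n in ((0, n0), (1, n1)):
                got = (test["CLASS"] == cls).sum()
                assert abs(got - 0.25 * n) <= 1

    def test_requires_both_classes(self, rng):
        t = _labeled(20, rng)
        t["CLASS"] = 0
        with pytest.raises(ValueError):
            split_train_test(t)


class TestTuneAndFit:
    def test_grid_of_size_one(self, rng):
        t = _labeled(60, rng)
        grids = {"bayes": {"var_smoothing": [2.5]}}
        model, best = tune_and_fit("bayes", t, grids=grids, seed=0)
        assert best == {"var_smoothing": 2.5}
        assert model.var_smoothing == 2.5

    def test_logreg_separable(self, rng):
        t = _labeled(120, rng, separation=10.0)
        model, _ = tune_and_fit("logreg", t, seed=0)
        x = t[[c for c in t.columns if c != "CLASS"]]
        assert (model.predict(x) == t["CLASS"]).all()

    def test_unknown_model(self, rng):
        with pytest.raises(ValueError):
            tune_and_fit("svm", _labeled(40, rng))

    def test_grid_choice_matches_brute_force(self, rng):
        # definitional oracle on a reduced grid with fixed folds
        t = _labeled(80, rng, separation=1.0)
        grid = {"var_smoothing": [0.5, 1.0, 5.0, 10.0]}
        _, best = tune_and_fit("bayes", t, cv_folds=5,
                               grids={"bayes": grid}, seed=7)
        x = t[[c for c in t.columns if c != "CLASS"]]
        y = t["CLASS"].to_numpy()
        scores = []
        for v in grid["var_smoothing"]:
            cv = StratifiedKFold(5, shuffle=True, random_state=7)
            s = cross_val_score(GaussianNB(var_smoothing=v), x, y,
                                scoring="accuracy", cv=cv).mean()
            scores.append(s)
        expected = grid["var_smoothing"][int(np.argmax(scores))]
        assert best["var_smoothing"] == expected


class TestMetrics:
    def test_hand_computed_confusion(self):
        m = metrics_from_confusion(tp=40, tn=45, fp=5, fn=10)
        acc, prec, rec, mcc = metrics_oracle(40, 45, 5, 10)
        assert m["accuracy"] == pytest.approx(acc) == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(prec) == pytest.approx(8 / 9)
        assert m["recall"] == pytest.approx(rec) == pytest.approx(0.80)
        assert m["mcc"] == pytest.approx(mcc)
        assert m["mcc"] == pytest.approx(0.7035, abs=5e-4)

    def test_mcc_agrees_with_sklearn(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        m = metrics_from_confusion(tp, tn, fp, fn)
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_perfect_predictions(self):
        m = metrics_from_confusion(tp=50, tn=50, fp=0, fn=0)
        assert all(v == 1.0 for v in m.values())

    def test_single_class_prediction_on_balanced(self):
        with pytest.warns(UserWarning):
            m = metrics_from_confusion(tp=0, tn=50, fp=0, fn=50)
        assert m["accuracy"] == 0.5
        assert m["mcc"] == 0.0
        assert m["recall"] == 0.0


class TestImportance:
    def test_constant_feature_zero_permutation_importance(self, rng):
        t = _labeled(100, rng)
        t["const"] = 1.0
        model, _ = tune_and_fit("bayes", t, seed=0)
        imp = importance(model, t, method="permutation", seed=0)
        row = imp.loc[imp["feature"] == "const", "importance"]
        assert float(row.iloc[0]) == 0.0

    def test_signal_feature_ranks_first(self, rng):
        t = _labeled(200, rng, separation=6.0)
        model, _ = tune_and_fit("logreg", t, seed=0)
        imp_perm = importance(model, t, method="permutation", seed=0)
        assert imp_perm.iloc[0]["feature"] == "f0"
        imp_coef = importance(model, t, method="coefficient")
        assert imp_coef.iloc[0]["feature"] == "f0"

    def test_deterministic_under_seed(self, rng):
        t = _labeled(80, rng)
        model, _ = tune_and_fit("bayes", t, seed=0)
        a = importance(model, t, seed=4)
        b = importance(model, t, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_method(self, rng):
        t = _labeled(40, rng)
        model, _ = tune_and_fit("bayes", t, seed=0)
        with pytest.raises(ValueError):
            importance(model, t, method="shap")


class TestEnsemble:
    @pytest.mark.parametrize("votes,expected", [
        ((0, 0, 0), False), ((0, 0, 1), False), ((0, 1, 0), False),
        ((1, 0, 0), False), ((0, 1, 1), True), ((1, 0, 1), True),
        ((1, 1, 0), True), ((1, 1, 1), True),
    ])
    def test_threshold_rule_truth_table(self, votes, expected):
        call = ensemble_call("q", dict(zip(ENSEMBLE_MODELS, votes)))
        assert call.divergent is expected

    def test_missing_vote_rejected(self):
        with pytest.raises(ValueError):
            ensemble_call("q", {"logreg": 1, "random_forest": 1})

    def test_bayes_vote_rejected(self):
        votes = {"bayes": 1, "logreg": 1, "random_forest": 1}
        with pytest.raises(ValueError):
            ensemble_call("q", votes)

    def test_ensemble_predict_frame(self, rng):
        t = _labeled(120, rng, separation=8.0)
        train, test = split_train_test(t, seed=0)
        models, _ = train_all(train, test, seed=0, models=ENSEMBLE_MODELS)
        preds = ensemble_predict(models, test)
        assert len(preds) == len(test)
        acc = (preds["divergent"].astype(int).to_numpy()
               == test["CLASS"].to_numpy()).mean()
        assert acc > 0.9  # trivially separable


class TestLeakage:
    def test_label_shuffle_is_chance(self, rng):
        t = _labeled(240, rng, separation=4.0)
        t["CLASS"] = rng.permutation(t["CLASS"].to_numpy())
        train, test = split_train_test(t, seed=0)
        model, _ = tune_and_fit("logreg", train, seed=0)
        m = evaluate(model, test)
        n = len(test)
        se = np.sqrt(0.25 / n)
        assert abs(m["accuracy"] - 0.5) <= 3 * se
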