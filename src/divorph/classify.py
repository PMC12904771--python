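"""Training, tuning, evaluation and the ensemble divergence vote.

Four classifiers: Gaussian naive Bayes ("bayes", the only common model
with a var-smoothing knob), logistic regression with built-in
cross-validated regularization ("logreg"), random forest and gradient
boosting. Hyperparameters are chosen by exhaustive grid search on mean
5-fold CV accuracy; the full published grids are available via
``full_grids()`` while the default grids are reduced to keep desk-scale
runtimes (documented divergence).

The ensemble labels a query *divergent* when at least two of the three
non-Bayes models vote divergent (Bayes is excluded for its consistently
poorer performance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB

from .features import NON_FEATURE_COLUMNS

__all__ = [
    "MODEL_NAMES",
    "ENSEMBLE_MODELS",
    "ModelReport",
    "EnsemblePrediction",
    "split_train_test",
    "tune_and_fit",
    "evaluate",
    "importance",
    "ensemble_call",
    "ensemble_predict",
    "default_grids",
    "full_grids",
    "train_all",
]

MODEL_NAMES = ("bayes", "logreg", "random_forest", "gradient_boosting")
#: Models whose votes form the ensemble (Bayes excluded).
ENSEMBLE_MODELS = ("logreg", "random_forest", "gradient_boosting")


def default_grids() -> dict[str, dict[str, list]]:
    """Reduced grids for desk-scale runs (same axes as the full sweep)."""
    return {
        "bayes": {"var_smoothing": [1.0, 5.0, 10.0, 20.0]},
        "random_forest": {
            "n_estimators": [51, 201],
            "max_features": ["sqrt", "log2"],
            "criterion": ["gini", "entropy"],
        },
        "gradient_boosting": {
            "n_estimators": [51, 201],
            "max_features": ["sqrt"],
            "learning_rate": [0.1, 0.5],
            "loss": ["log_loss"],
        },
    }


def full_grids() -> dict[str, dict[str, list]]:
    """The complete replication grids (slow; hours at catalogue scale).

    Estimator counts swept 1 to 1000 in steps of 50 are the literal
    arithmetic sequence {1, 51, ..., 951}; the Bayes var-smoothing sweep
    is 1 to 20 in steps of 1, which is unusually large for that parameter
    (a log-scale grid is the common alternative) but kept for fidelity.
    """
    estimators = list(range(1, 1000, 50))
    return {
        "bayes": {"var_smoothing": [float(v) for v in range(1, 21)]},
        "random_forest": {
            "n_estimators": estimators,
            "max_features": ["sqrt", "log2"],
            "criterion": ["gini", "entropy", "log_loss"],
        },
        "gradient_boosting": {
            "n_estimators": estimators,
            "max_features": ["sqrt", "log2"],
            "learning_rate": [round(0.1 * k, 1) for k in range(1, 11)],
            "loss": ["log_loss", "exponential"],
        },
    }


@dataclass
class ModelReport:
    """Fitted-model metadata: best hyperparameters, the four test metrics
    and ranked feature importances."""

    model_name: str
    best_params: dict
    metrics: dict[str, float]
    importances: pd.DataFrame | None = None
    importance_method: str | None = None


@dataclass(frozen=True)
class EnsemblePrediction:
    query_id: str
    votes: dict[str, int]
    divergent: bool


def _xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    cols = [c for c in table.columns if c not in NON_FEATURE_COLUMNS]
    return table[cols], table["CLASS"].to_numpy()


def split_train_test(
    table: pd.DataFrame,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 75/25 (by default) split on CLASS, reproducible by seed."""
    counts = table["CLASS"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 rows")
    train, test = train_test_split(
        table,
        test_size=test_fraction,
        stratify=table["CLASS"],
        random_state=seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def tune_and_fit(
    model_name: str,
    train: pd.DataFrame,
    cv_folds: int = 5,
    grids: Mapping[str, dict] | None = None,
    seed: int = 0,
):
    """Grid-search a model by mean CV accuracy and refit on the full
    training table. Returns (fitted estimator, best hyperparameters).

    Ties go to the first configuration in grid order. Logistic regression
    uses its built-in cross-validated regularization path instead of an
    external grid.
    """
    x, y = _xy(train)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if model_name == "logreg":
        model = LogisticRegressionCV(cv=cv, scoring="accuracy", max_iter=5000)
        with warnings.catch_warnings():
            # sklearn 1.9 emits FutureWarnings about attribute/default
            # changes in LogisticRegressionCV; neither affects results
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(x, y)
        return model, {"C": float(model.C_[0])}
    grids = grids or default_grids()
    if model_name not in grids:
        raise ValueError(f"unknown model {model_name!r}")
    grid = grids[model_name]
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("grids must be non-empty")
    base = {
        "bayes": GaussianNB(),
        "random_forest": RandomForestClassifier(random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
    }[model_name]
    search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, n_jobs=1)
    search.fit(x, y)
    return search.best_estimator_, dict(search.best_params_)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall and MCC from raw counts.

    Positive class is the divergent/simulated one throughout. Undefined
    denominators yield 0 with a warning (documented convention).
    """
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          stacklevel=3)
            return 0.0
        return num / den

    accuracy = (tp + tn) / n
    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, denom, "MCC")
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "mcc": mcc}


def evaluate(model, test: pd.DataFrame) -> dict[str, float]:
    """Test-set metrics for a fitted model."""
    if len(test) == 0:
        raise ValueError("test table is empty")
    x, y = _xy(test)
    pred = model.predict(x)
    return metrics_from_confusion(*_confusion(y, pred))


def importance(
    model,
    test: pd.DataFrame,
    method: str = "permutation",
    n_repeats: int = 10,
    seed: int = 0,
    top: int = 10,
) -> pd.DataFrame:
    """Ranked feature importances.

    ``permutation``: mean accuracy drop over ``n_repeats`` shuffles per
    feature. ``coefficient``: signed linear coefficients ranked by
    absolute value (logistic regression).
    """
    x, y = _xy(test)
    if method == "permutation":
        res = permutation_importance(
            model, x, y, scoring="accuracy",
            n_repeats=n_repeats, random_state=seed,
        )
        df = pd.DataFrame({
            "feature": x.columns,
            "importance": res.importances_mean,
        }).sort_values("importance", ascending=False, kind="stable")
    elif method == "coefficient":
        coefs = np.asarray(model.coef_).ravel()
        df = pd.DataFrame({"feature": x.columns, "importance": coefs})
        df = df.reindex(
            df["importance"].abs().sort_values(ascending=False, kind="stable").index
        )
    else:
        raise ValueError(f"unknown importance method {method!r}")
    return df.head(top).reset_index(drop=True)


def ensemble_call(
    query_id: str, votes: Mapping[str, int]
) -> EnsemblePrediction:
    """Majority-of-three vote: divergent iff >= 2 divergent votes from
    exactly the non-Bayes models."""
    if set(votes) != set(ENSEMBLE_MODELS):
        missing = set(ENSEMBLE_MODELS) ^ set(votes)
        raise ValueError(f"expected votes from {ENSEMBLE_MODELS}, "
                         f"mismatch on {sorted(missing)}")
    total = sum(int(bool(v)) for v in votes.values())
    return EnsemblePrediction(query_id=query_id, votes=dict(votes),
                              divergent=total >= 2)


def ensemble_predict(
    models: Mapping[str, object], table: pd.DataFrame
) -> pd.DataFrame:
    """Apply the three ensemble models to a feature table.

    Returns a frame with per-model votes and the final divergent flag.
    """
    x, _ = (table[[c for c in table.columns if c not in NON_FEATURE_COLUMNS]],
            None)
    ids = (table["query_id"] if "query_id" in table.columns
           else pd.Series(range(len(table)), name="query_id").astype(str))
    votes = {name: models[name].predict(x) for name in ENSEMBLE_MODELS}
    rows = []
    for i, qid in enumerate(ids):
        call = ensemble_call(str(qid), {m: int(votes[m][i])
                                        for m in ENSEMBLE_MODELS})
        rows.append({"query_id": call.query_id, **call.votes,
                     "divergent": call.divergent})
    return pd.DataFrame(rows)


def train_all(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cv_folds: int = 5,
    grids: Mapping[str, dict] | None = None,
    seed: int = 0,
    models: Sequence[str] = MODEL_NAMES,
) -> tuple[dict[str, object], dict[str, ModelReport]]:
    """Tune, fit and evaluate all requested models."""
    fitted: dict[str, object] = {}
    reports: dict[str, ModelReport] = {}
    for name in models:
        model, best = tune_and_fit(name, train, cv_folds, grids, seed)
        mets = evaluate(model, test)
        method = "coefficient" if name == "logreg" else "permutation"
        imp = importance(model, test, method=method, seed=seed)
        fitted[name] = model
        reports[name] = ModelReport(
            model_name=name, best_params=best, metrics=mets,
            importances=imp, importance_method=method,
        )
    return fitted, reports
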