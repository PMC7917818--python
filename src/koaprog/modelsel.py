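"""Classifier comparison over increasing feature-count prefixes.

Six classifiers (gradient boosting, L2 logistic regression, multilayer
perceptron, Gaussian naive Bayes, random forest, SVM) are tuned by
exhaustive grid search with stratified 3-fold CV on a 70/30 stratified
split, evaluated on the held-out 30 % at every prefix of the vote ranking
(default step: 2 features), then the best models are re-evaluated at step
1 in a neighborhood of their accuracy peak and the final model is the one
with maximum refined held-out accuracy (ties: fewer features, then a
fixed model order).

The same train/test split is reused for every model and feature count so
the accuracy curves are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    ParameterGrid,
    StratifiedKFold,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

#: Residual tie-break order for final model selection.
MODEL_ORDER = ("logreg", "svm", "nn", "gbm", "rf", "nbg")


def make_model(model_id: str, seed: int = 0):
    if model_id == "gbm":
        return GradientBoostingClassifier(random_state=seed)
    if model_id == "logreg":
        return LogisticRegression(max_iter=2000)  # default penalty is L2
    if model_id == "nn":
        return MLPClassifier(random_state=seed, max_iter=300)
    if model_id == "nbg":
        return GaussianNB()
    if model_id == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model_id == "svm":
        return SVC(random_state=seed)
    raise ValueError(f"unknown model id {model_id!r}")


_C_RANGE = [0.001, 0.01, 0.1] + list(range(1, 11))


def model_grid(model_id: str, density: str = "reduced") -> list[dict]:
    """Hyperparameter grid for one model.

    ``density="full"`` is the complete reference search space (tens of thousands
    of fits across models — a flagged long-running mode); the default
    ``"reduced"`` keeps a small representative sub-grid per model so a
    whole accuracy curve fits desk-scale budgets.
    """
    if density not in ("reduced", "full"):
        raise ValueError("density must be 'reduced' or 'full'")
    full = density == "full"
    if model_id == "gbm":
        grid = {
            "n_estimators": list(range(10, 501, 10)) if full else [50, 100],
            "max_depth": list(range(1, 11)) if full else [2, 3],
            "min_samples_split": [2, 5, 10] if full else [2],
            "min_samples_leaf": [1, 2, 4] if full else [1],
            "max_features": [None, "log2"] if full else [None],
        }
    elif model_id == "logreg":
        grid = {
            "C": _C_RANGE if full else [0.01, 0.1, 1, 10],
            "solver": ["newton-cg", "lbfgs", "sag", "saga"] if full else ["lbfgs"],
            "warm_start": [False, True] if full else [False],
        }
    elif model_id == "nn":
        layers = [50, 100, 200]
        hidden = (
            [(a,) for a in layers]
            + [(a, b) for a in layers for b in layers]
            + [(a, b, c) for a in layers for b in layers for c in layers]
            if full
            else [(50,)]
        )
        grid = {
            "hidden_layer_sizes": hidden,
            "activation": ["relu", "tanh"] if full else ["relu"],
            "alpha": [0.0001, 0.05],
            "solver": ["adam", "sgd", "lbfgs"] if full else ["adam"],
            "learning_rate": ["constant", "adaptive"] if full else ["constant"],
        }
    elif model_id == "nbg":
        grid = {}
    elif model_id == "rf":
        grid = {
            "n_estimators": list(range(10, 501, 10)) if full else [100],
            "max_depth": list(range(1, 11)) if full else [3, 10],
            "min_samples_split": [2, 5, 10] if full else [2],
            "min_samples_leaf": [1, 2, 4] if full else [1],
            "max_features": [None, "log2"] if full else ["log2"],
            "bootstrap": [True, False] if full else [True],
        }
    elif model_id == "svm":
        grid = {
            "C": _C_RANGE if full else [0.1, 1, 10],
            "kernel": ["linear", "poly", "sigmoid", "rbf"] if full else ["linear", "rbf"],
        }
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    return list(ParameterGrid(grid))


# ---------------------------------------------------------------------------
# Split / tune
# ---------------------------------------------------------------------------

def split_data(X, y, train_fraction: float = 0.7, seed: int = 0):
    """Stratified train/test split. Returns (train_index, test_index)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(y)
    if min(np.bincount(y)) < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(tr), np.sort(te)


def tune_and_fit(
    model_id: str,
    X_train,
    y_train,
    folds: int = 3,
    grid_density: str = "reduced",
    seed: int = 0,
):
    """Exhaustive grid search (stratified CV accuracy), refit on all
    training rows.  Ties go to the first configuration in grid order; a
    configuration that fails to train scores 0 and is skipped, not fatal.

    Returns (fitted estimator, best params, best mean CV accuracy).
    """
    grid = model_grid(model_id, grid_density)
    est = make_model(model_id, seed)
    # one singleton sub-grid per configuration keeps the deterministic
    # grid order (ties resolve to the first configuration)
    param_grid = [{k: [v] for k, v in cfg.items()} for cfg in grid]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, param_grid, scoring="accuracy", cv=cv,
                          error_score=0, refit=True, n_jobs=1)
    X_train = np.asarray(X_train, dtype=float)
    search.fit(X_train, np.asarray(y_train))
    return search.best_estimator_, dict(search.best_params_), float(search.best_score_)


# ---------------------------------------------------------------------------
# Accuracy curves
# ---------------------------------------------------------------------------

@dataclass
class AccuracyCurve:
    model: str
    points: list[tuple[int, float, dict]] = field(default_factory=list)  # (n_features, test acc, params)
    step: int = 2

    def summaries(self) -> dict[str, float]:
        acc = np.array([p[1] for p in self.points], dtype=float)
        return {
            "max": float(acc.max()),
            "min": float(acc.min()),
            "mean": float(acc.mean()),
            "sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        }

    @property
    def argmax_count(self) -> int:
        best = max(self.points, key=lambda p: (p[1], -p[0]))
        return best[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "n_features": [p[0] for p in self.points],
                "accuracy": [p[1] for p in self.points],
                "params": [json.dumps(p[2], sort_keys=True) for p in self.points],
            }
        )


@dataclass
class BestModel:
    model: str
    n_features: int
    accuracy: float
    params: dict
    features: list[str]
    estimator: object = None
    coef: np.ndarray | None = None  # linear models only
    intercept: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "n_features": self.n_features,
            "accuracy": self.accuracy,
            "params": self.params,
            "features": self.features,
        }
        if self.coef is not None:
            payload["coef"] = [float(v) for v in self.coef]
            payload["intercept"] = float(self.intercept)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _eval_at_count(
    model_id, count, ranking, X_train, X_test, y_train, y_test, folds,
    grid_density, seed,
):
    feats = ranking[:count]
    est, params, _cv = tune_and_fit(
        model_id, X_train[feats], y_train, folds=folds,
        grid_density=grid_density, seed=seed,
    )
    acc = float(
        (est.predict(np.asarray(X_test[feats], dtype=float)) == np.asarray(y_test)).mean()
    )
    return acc, params, est


def evaluate_curve(
    model_ids,
    ranking: list[str],
    X: pd.DataFrame,
    y,
    step: int = 2,
    max_features: int | None = None,
    train_fraction: float = 0.7,
    folds: int = 3,
    grid_density: str = "reduced",
    seed: int = 0,
    split=None,
) -> dict[str, AccuracyCurve]:
    """Held-out accuracy vs. number of top-ranked features, per model.

    One stratified split (shared across models and counts) is drawn unless
    ``split=(train_idx, test_idx)`` is supplied.
    """
    if not ranking:
        raise ValueError("ranking is empty")
    missing = [f for f in ranking if f not in X.columns]
    if missing:
        raise ValueError(f"ranked features absent from X: {missing[:5]}")
    y = np.asarray(y)
    tr, te = split if split is not None else split_data(X, y, train_fraction, seed)
    X_train, X_test = X.iloc[tr], X.iloc[te]
    y_train, y_test = y[tr], y[te]

    limit = min(len(ranking), max_features or len(ranking))
    counts = list(range(step, limit + 1, step))
    if not counts:
        counts = [limit]
    curves: dict[str, AccuracyCurve] = {}
    for model_id in model_ids:
        curve = AccuracyCurve(model=model_id, step=step)
        for count in counts:
            acc, params, _ = _eval_at_count(
                model_id, count, ranking, X_train, X_test, y_train, y_test,
                folds, grid_density, seed,
            )
            curve.points.append((count, acc, params))
        curves[model_id] = curve
    return curves


def refine_and_select(
    curves: dict[str, AccuracyCurve],
    ranking: list[str],
    X: pd.DataFrame,
    y,
    split,
    radius: int = 10,
    fine_step: int = 1,
    top_n: int = 2,
    folds: int = 3,
    grid_density: str = "reduced",
    seed: int = 0,
) -> tuple[BestModel, dict[str, AccuracyCurve]]:
    """Step-1 re-evaluation around each top model's accuracy peak.

    The final winner maximizes refined held-out accuracy; ties prefer
    fewer features, then the fixed model order.
    """
    if not curves:
        raise ValueError("no curves to refine")
    y = np.asarray(y)
    tr, te = split
    X_train, X_test = X.iloc[tr], X.iloc[te]
    y_train, y_test = y[tr], y[te]

    by_peak = sorted(
        curves.values(),
        key=lambda c: (-c.summaries()["max"], MODEL_ORDER.index(c.model)),
    )
    refined: dict[str, AccuracyCurve] = {}
    candidates: list[tuple[float, int, int, str, dict, object]] = []
    for curve in by_peak[: max(1, top_n)]:
        center = curve.argmax_count
        lo = max(1, center - radius)
        hi = min(len(ranking), center + radius)
        if lo > hi:
            raise ValueError("empty refinement neighborhood")
        fine = AccuracyCurve(model=curve.model, step=fine_step)
        for count in range(lo, hi + 1, fine_step):
            acc, params, est = _eval_at_count(
                curve.model, count, ranking, X_train, X_test, y_train, y_test,
                folds, grid_density, seed,
            )
            fine.points.append((count, acc, params))
            candidates.append(
                (-acc, count, MODEL_ORDER.index(curve.model), curve.model, params, est)
            )
        refined[curve.model] = fine
    candidates.sort(key=lambda t: t[:3])
    neg_acc, n_features, _, model_id, params, est = candidates[0]
    best = BestModel(
        model=model_id,
        n_features=n_features,
        accuracy=-neg_acc,
        params=params,
        features=ranking[:n_features],
        estimator=est,
    )
    if model_id == "logreg":
        best.coef = est.coef_[0].copy()
        best.intercept = float(est.intercept_[0])
    return best, refined


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class IncrementalModelSelector(BaseEstimator):
    """Fit the whole curve-and-refine protocol as one estimator.

    ``fit(X, y, ranking=...)`` draws one stratified 70/30 split, builds an
    accuracy curve per model over prefixes of ``ranking`` (step
    ``step``), refines the best ``top_n`` models at step 1 within
    ``radius`` of their peak, and keeps the winner.

    Attributes: ``curves_``, ``refined_curves_``, ``best_``,
    ``train_index_``, ``test_index_``.
    """

    def __init__(
        self,
        models=MODEL_ORDER,
        step: int = 2,
        max_features: int | None = None,
        radius: int = 10,
        top_n: int = 2,
        folds: int = 3,
        grid_density: str = "reduced",
        train_fraction: float = 0.7,
        random_state: int = 0,
    ):
        self.models = models
        self.step = step
        self.max_features = max_features
        self.radius = radius
        self.top_n = top_n
        self.folds = folds
        self.grid_density = grid_density
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, ranking: list[str] | None = None):
        if ranking is None:
            raise ValueError("fit requires ranking=<ordered feature ids>")
        y = np.asarray(y)
        tr, te = split_data(X, y, self.train_fraction, self.random_state)
        self.train_index_, self.test_index_ = tr, te
        limit = min(len(ranking), self.max_features or len(ranking))
        self.ranking_ = list(ranking[:limit])
        self.curves_ = evaluate_curve(
            self.models, self.ranking_, X, y,
            step=self.step, max_features=limit, folds=self.folds,
            grid_density=self.grid_density, seed=self.random_state,
            split=(tr, te),
        )
        self.best_, self.refined_curves_ = refine_and_select(
            self.curves_, self.ranking_, X, y, (tr, te),
            radius=self.radius, top_n=self.top_n, folds=self.folds,
            grid_density=self.grid_density, seed=self.random_state,
        )
        return self

    def predict(self, X: pd.DataFrame):
        feats = self.best_.features
        return self.best_.estimator.predict(np.asarray(X[feats], dtype=float))

    def score(self, X: pd.DataFrame, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    def curves_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.curves_.values()]
        frames += [c.to_frame().assign(model=c.model + "_refined")
                   for c in self.refined_curves_.values()]
        return pd.concat(frames, ignore_index=True)
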