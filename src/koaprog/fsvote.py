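"""Ensemble feature selection by majority voting.

Six scorers — two filters (absolute point-biserial/Pearson correlation and
the chi-squared independence statistic), one wrapper (recursive feature
elimination around an L2 logistic regression) and three embedded
importances (random forest impurity decrease, LightGBM split gain,
|logistic coefficient|) — each nominate a top-K subset.  A feature's vote
count V_j is the number of techniques nominating it; the final ranking is
by descending votes, ties broken by the importance assigned by the
best-performing technique (highest 3-fold CV accuracy of a reference L2
logistic classifier on its subset), residual ties by feature id.  Only
features with at least one vote are ranked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

#: Fixed technique order; also the deterministic tie-break for the winner.
TECHNIQUES = ("pearson", "chi2", "rfe", "rf", "gbm", "l2logreg")


@dataclass
class FsResult:
    """One technique's nomination: selected subset plus importance scores."""

    technique: str
    selected: list[str]
    importance: dict[str, float]


@dataclass
class VoteTally:
    votes: dict[str, int]
    winner: str
    ranking: list[str]
    winner_importance: dict[str, float] = field(default_factory=dict)


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{i:04d}" for i in range(X.shape[1])])


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    uniq = np.unique(y)
    if len(uniq) != 2 or not set(uniq) <= {0, 1}:
        raise ValueError("y must be binary 0/1 with both classes present")
    return y.astype(int)


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

def filter_scores(X, y, method: str) -> dict[str, float]:
    """Filter importances: |point-biserial r| or the chi-squared statistic.

    Constant features score 0 under both filters.  The chi-squared filter
    treats per-class feature sums as observed counts against their
    class-proportional expectation and requires non-negative values
    (guaranteed after [0, 1] normalization).
    """
    frame = _frame(X)
    y = _check_binary(y)
    if method == "pearson":
        arr = frame.to_numpy(dtype=float)
        yc = y - y.mean()
        xc = arr - arr.mean(axis=0)
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
        return dict(zip(frame.columns, np.abs(r)))
    if method == "chi2":
        arr = frame.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("chi-squared filter requires non-negative features")
        stats, _ = _sk_chi2(arr, y)
        return dict(zip(frame.columns, np.nan_to_num(stats, nan=0.0)))
    raise ValueError(f"unknown filter method {method!r}")


def _reference_logreg(seed: int | None = None) -> LogisticRegression:
    # default penalty is L2
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)


def rfe_rank(
    X,
    y,
    target_size: int,
    step_fraction: float = 0.10,
    seed: int = 0,
) -> FsResult:
    """Recursive feature elimination around an L2 logistic regression.

    Each round drops the ``max(1, ceil(step_fraction * remaining))``
    features with the smallest |coefficient| (ties by feature id) and
    refits, continuing past the target so every feature gets an
    elimination rank; importance is the (0-based) elimination order, so
    later-eliminated features score higher and the ``target_size``
    survivors score highest.
    """
    frame = _frame(X)
    y = _check_binary(y)
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    names = list(frame.columns)
    if target_size >= len(names):
        est = _reference_logreg().fit(frame.to_numpy(dtype=float), y)
        imp = dict(zip(names, np.abs(est.coef_[0])))
        return FsResult("rfe", names, imp)

    remaining = list(names)
    importance: dict[str, float] = {}
    order = 0
    selected: list[str] | None = None
    while len(remaining) > 1:
        est = _reference_logreg().fit(frame[remaining].to_numpy(dtype=float), y)
        coefs = np.abs(est.coef_[0])
        n_drop = max(1, math.ceil(step_fraction * len(remaining)))
        n_drop = min(n_drop, len(remaining) - 1)
        if selected is None and len(remaining) - n_drop < target_size:
            n_drop = len(remaining) - target_size
            if n_drop == 0:
                selected = list(remaining)
                continue
        drop_idx = sorted(range(len(remaining)), key=lambda i: (coefs[i], remaining[i]))[
            :n_drop
        ]
        for i in sorted(drop_idx, reverse=True):
            importance[remaining[i]] = float(order)
            order += 1
            del remaining[i]
        if selected is None and len(remaining) == target_size:
            selected = list(remaining)
    importance[remaining[0]] = float(order)
    if selected is None:
        selected = list(remaining)
    return FsResult("rfe", selected, importance)


def embedded_importance(X, y, model: str, seed: int = 0) -> dict[str, float]:
    """Model-internal importances: rf impurity decrease, LightGBM split
    gain, or |L2-logistic coefficient|."""
    frame = _frame(X)
    y = _check_binary(y)
    arr = frame.to_numpy(dtype=float)
    if model == "rf":
        est = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        est.fit(arr, y)
        values = est.feature_importances_
    elif model == "gbm":
        est = LGBMClassifier(
            n_estimators=100,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
            n_jobs=1,
        )
        est.fit(arr, y)
        values = est.booster_.feature_importance(importance_type="gain")
    elif model == "l2logreg":
        est = _reference_logreg(seed).fit(arr, y)
        values = np.abs(est.coef_[0])
    else:
        raise ValueError(f"unknown embedded model {model!r}")
    return dict(zip(frame.columns, np.asarray(values, dtype=float)))


def select_top(importance: dict[str, float], k: int) -> list[str]:
    """Top-k feature ids by descending importance, ties by feature id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(importance, key=lambda f: (-importance[f], f))
    return ranked[: min(k, len(ranked))]


def technique_cv_score(
    selected: list[str], X, y, folds: int = 3, seed: int = 0
) -> float:
    """Mean stratified CV accuracy of the reference L2 logistic classifier
    restricted to one technique's subset."""
    frame = _frame(X)
    y = _check_binary(y)
    if min(np.bincount(y)) < folds:
        raise ValueError("a CV fold would contain a single class")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        _reference_logreg(), frame[selected].to_numpy(dtype=float), y, cv=cv,
        scoring="accuracy",
    )
    return float(scores.mean())


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def vote_rank(results: list[FsResult], winner: str) -> VoteTally:
    """Tally votes over techniques and rank the voted features.

    V_j counts the techniques selecting feature j.  Ranking: descending
    V_j, ties by descending winner-technique importance, residual ties by
    feature id.  Features with zero votes are excluded.
    """
    ids = [r.technique for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate technique ids")
    if winner not in ids:
        raise ValueError(f"winner {winner!r} not among the results")
    votes: dict[str, int] = {}
    for r in results:
        for f in r.selected:
            votes[f] = votes.get(f, 0) + 1
    w_imp = next(r for r in results if r.technique == winner).importance
    ranking = sorted(
        votes, key=lambda f: (-votes[f], -w_imp.get(f, -np.inf), f)
    )
    return VoteTally(votes=votes, winner=winner, ranking=ranking, winner_importance=dict(w_imp))


class VotingFeatureSelector(BaseEstimator):
    """Sklearn-style selector running the six-technique vote.

    Parameters
    ----------
    k : int
        Subset size each technique nominates (clipped to the number of
        available features).  The default 200 lets the downstream accuracy
        curve extend past the feature counts where accuracy typically peaks.
    cv : int
        Folds for the winner-deciding CV score.
    random_state : int
        Base seed; each stochastic scorer derives a fixed offset from it,
        so the six scorers are order-invariant.

    Attributes
    ----------
    results_ : dict technique -> FsResult
    cv_scores_ : dict technique -> float
    winner_ : str
    votes_ : dict feature -> int
    ranking_ : list of feature ids (descending votes)
    """

    def __init__(self, k: int = 200, cv: int = 3, random_state: int = 0):
        self.k = k
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        frame = _frame(X)
        y = _check_binary(y)
        k = min(self.k, frame.shape[1])
        seed = self.random_state
        results: dict[str, FsResult] = {}
        for i, tech in enumerate(TECHNIQUES):
            tech_seed = seed + 100 + i
            if tech in ("pearson", "chi2"):
                imp = filter_scores(frame, y, tech)
                results[tech] = FsResult(tech, select_top(imp, k), imp)
            elif tech == "rfe":
                results[tech] = rfe_rank(frame, y, k, seed=tech_seed)
            else:
                imp = embedded_importance(frame, y, tech, seed=tech_seed)
                results[tech] = FsResult(tech, select_top(imp, k), imp)
        self.results_ = results
        self.cv_scores_ = {
            tech: technique_cv_score(results[tech].selected, frame, y, folds=self.cv,
                                     seed=seed)
            for tech in TECHNIQUES
        }
        # best CV accuracy; ties resolved by the fixed technique order
        self.winner_ = max(TECHNIQUES, key=lambda t: (self.cv_scores_[t], -TECHNIQUES.index(t)))
        tally = vote_rank([results[t] for t in TECHNIQUES], self.winner_)
        self.tally_ = tally
        self.votes_ = tally.votes
        self.ranking_ = tally.ranking
        self.feature_names_in_ = list(frame.columns)
        return self

    def transform(self, X):
        frame = _frame(X)
        return frame[self.ranking_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def ranking_frame(self) -> pd.DataFrame:
        """Rank, feature id, votes, winner-technique importance."""
        w_imp = self.tally_.winner_importance
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking_) + 1),
                "feature": self.ranking_,
                "votes": [self.votes_[f] for f in self.ranking_],
                "winner_importance": [w_imp.get(f, np.nan) for f in self.ranking_],
            }
        )
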