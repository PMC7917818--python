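"""Shapley-value attribution for the selected classifier.

For a linear margin eta(x) = w·x + b with an independent background
distribution, the interventional Shapley value has the closed form

    phi_ij = w_j * (x_ij - xbar_j),

with xbar the background (training) feature means and base value
eta(xbar).  Local accuracy holds exactly: sum_j phi_ij = eta(x_i) -
base.  A Monte-Carlo permutation sampler provides the model-agnostic
route: feature orderings are sampled, features are switched from a random
background row to the explained row in order, and each feature is
credited its marginal margin change; the average is an unbiased estimate
of the same Shapley value.

Two summary rankings mirror the standard summary plots: per-feature sum
of |phi| over samples and per-feature mean |phi|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class ShapMatrix:
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    background_mean: np.ndarray
    feature_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


@dataclass
class FeatureImpact:
    sum_abs: pd.Series
    mean_abs: pd.Series
    ranking_sum: list[str]
    ranking_mean: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ranking_sum,
                "sum_abs_shap": self.sum_abs[self.ranking_sum].to_numpy(),
                "mean_abs_shap": self.mean_abs[self.ranking_sum].to_numpy(),
            }
        )


def linear_shap(weights, intercept, X, background_mean, feature_names=None) -> ShapMatrix:
    """Exact Shapley attributions of a linear margin against mean background."""
    w = np.asarray(weights, dtype=float)
    X = np.asarray(X, dtype=float)
    xbar = np.asarray(background_mean, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(w) or len(xbar) != len(w):
        raise ValueError("weights, X columns and background mean must align")
    phi = w[None, :] * (X - xbar[None, :])
    base = float(w @ xbar + intercept)
    names = list(feature_names) if feature_names is not None else [
        f"f{i:04d}" for i in range(len(w))
    ]
    return ShapMatrix(values=phi, base_value=base, background_mean=xbar, feature_names=names)


def permutation_shap(
    predict_margin,
    x,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    return_se: bool = False,
):
    """Monte-Carlo Shapley estimate for one row under any margin function.

    Each draw picks a background row and a feature ordering, switches
    features from background to ``x`` in that order, and credits every
    feature its marginal change of the margin.  With ``return_se`` the
    per-feature Monte-Carlo standard error (std of per-draw contributions
    / sqrt(draws)) is returned alongside the estimates.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or len(background) == 0:
        raise ValueError("background must be a non-empty 2-D array")
    x = np.asarray(x, dtype=float)
    m = background.shape[1]
    rng = np.random.default_rng(seed)
    total = np.zeros(m)
    total_sq = np.zeros(m)
    for _ in range(n_permutations):
        b = background[rng.integers(len(background))]
        order = rng.permutation(m)
        # build all m+1 intermediate rows, evaluate the margin in one call
        rows = np.tile(b, (m + 1, 1))
        for step, j in enumerate(order, start=1):
            rows[step:, j] = x[j]
        margins = np.asarray(predict_margin(rows), dtype=float)
        if margins.shape != (m + 1,):
            raise ValueError("predict_margin must return one margin per row")
        contrib = np.empty(m)
        contrib[order] = np.diff(margins)
        total += contrib
        total_sq += contrib**2
    phi = total / n_permutations
    if not return_se:
        return phi
    var = np.maximum(total_sq / n_permutations - phi**2, 0.0)
    se = np.sqrt(var / n_permutations)
    return phi, se


def rank_impact(shap: ShapMatrix, feature_values: pd.DataFrame | None = None):
    """Sum-of-|phi| and mean-|phi| summaries with their rankings.

    If ``feature_values`` is given, also returns a long-format beeswarm
    export (per-sample phi with the normalized feature value for coloring).
    """
    if shap.values.size == 0:
        raise ValueError("empty attribution matrix")
    absphi = np.abs(shap.values)
    sum_abs = pd.Series(absphi.sum(axis=0), index=shap.feature_names)
    mean_abs = pd.Series(absphi.mean(axis=0), index=shap.feature_names)
    ranking_sum = sorted(shap.feature_names, key=lambda f: (-sum_abs[f], f))
    ranking_mean = sorted(shap.feature_names, key=lambda f: (-mean_abs[f], f))
    impact = FeatureImpact(sum_abs, mean_abs, ranking_sum, ranking_mean)
    if feature_values is None:
        return impact
    long = shap.to_frame().melt(var_name="feature", value_name="shap_value")
    long["feature_value"] = (
        feature_values[shap.feature_names].to_numpy().T.reshape(-1)
    )
    return impact, long


class LinearShapExplainer(BaseEstimator):
    """Sklearn-style wrapper around the closed-form linear attribution.

    ``fit(background_X)`` stores the per-feature background means;
    ``shap_values(X)`` returns the :class:`ShapMatrix` for new rows.
    Weights can be given directly or taken from a fitted linear model
    exposing ``coef_``/``intercept_``.
    """

    def __init__(self, weights=None, intercept: float = 0.0, model=None):
        self.weights = weights
        self.intercept = intercept
        self.model = model

    def _coefs(self) -> tuple[np.ndarray, float]:
        if self.model is not None:
            return np.ravel(self.model.coef_), float(np.ravel(self.model.intercept_)[0])
        if self.weights is None:
            raise ValueError("provide weights or a fitted linear model")
        return np.asarray(self.weights, dtype=float), float(self.intercept)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.background_mean_ = X.mean(axis=0)
        w, _ = self._coefs()
        if X.shape[1] != len(w):
            raise ValueError("background and weights disagree on dimensionality")
        return self

    def shap_values(self, X, feature_names=None) -> ShapMatrix:
        if isinstance(X, pd.DataFrame) and feature_names is None:
            feature_names = list(X.columns)
        w, b = self._coefs()
        return linear_shap(w, b, np.asarray(X, dtype=float), self.background_mean_,
                           feature_names)
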