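"""End-to-end pipeline: cohort -> labels -> ranking -> model -> attributions.

``run_all`` wires the stages together with leakage-safe defaults: the
progression labels come only from the trajectory table; preprocessing
statistics, feature-selection votes and hyperparameter tuning are all
estimated on the training split of the balanced cohort and applied
unchanged to the held-out split.  Every stage seed derives from one master
seed, so two runs with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .explain import LinearShapExplainer, ShapMatrix, permutation_shap, rank_impact
from .fsvote import VotingFeatureSelector
from .labeling import ProgressionLabeler
from .modelsel import MODEL_ORDER, IncrementalModelSelector, split_data
from .preprocess import CohortPreprocessor
from .synthdata import CohortSpec, generate_cohort

DEFAULT_CONFIG: dict = {
    "cohort": {"n_subjects": 2000},
    "labeling": {"strategy": "combined", "method": "kmeans", "k": 2},
    "selection": {"k": 200, "scope": "train"},
    "evaluation": {
        "models": list(MODEL_ORDER),
        "step": 2,
        "max_features": 60,
        "radius": 10,
        "top_n": 2,
        "folds": 3,
        "grid_density": "reduced",
        "train_fraction": 0.7,
    },
    "explain": {"rows": "test", "n_permutations": 100, "max_rows": 50},
    "preprocess": {"threshold": 0.20},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        cfg.setdefault(section, {}).update(values)
    return cfg


@dataclass
class PipelineResult:
    config: dict
    seed: int
    cohort: object
    labeler: ProgressionLabeler
    preprocessor: CohortPreprocessor
    selector: VotingFeatureSelector
    model_selector: IncrementalModelSelector
    shap: ShapMatrix
    impact: object
    summary: dict


def _margin_fn(estimator):
    if hasattr(estimator, "decision_function"):
        return lambda X: np.ravel(estimator.decision_function(X))

    def log_odds(X):
        p = estimator.predict_proba(X)[:, 1]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    return log_odds


def run_all(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on a synthetic cohort.

    Stage seeds are fixed offsets of ``seed``.  When ``out_dir`` is given,
    writes labels.csv, ranking.csv, curves.csv, best_model.json,
    shap_values.csv, impact.csv and report.json.
    """
    cfg = merge_config(config)

    spec = CohortSpec(seed=seed, **cfg["cohort"])
    cohort = generate_cohort(spec)

    labeler = ProgressionLabeler(random_state=seed + 10, **cfg["labeling"])
    labeler.fit(cohort.trajectories)
    if labeler.classes_ is None:
        raise RuntimeError("labeling did not produce a binary solution")
    ids = labeler.balanced_ids_
    y = labeler.classes_.loc[ids].to_numpy()

    features = cohort.features
    balanced = CohortTable(
        data=features.data.loc[ids],
        kinds=features.kinds,
        categories=features.categories,
        provenance=list(features.provenance),
    )

    split_seed = seed + 20
    train_frac = cfg["evaluation"]["train_fraction"]
    tr, te = split_data(balanced.data, y, train_fraction=train_frac, seed=split_seed)

    prep = CohortPreprocessor(threshold=cfg["preprocess"]["threshold"])
    train_table = CohortTable(
        data=balanced.data.iloc[tr],
        kinds=balanced.kinds,
        categories=balanced.categories,
        provenance=list(balanced.provenance),
    )
    prep.fit(train_table)
    X = prep.transform(balanced).data  # train statistics applied to all rows

    selector = VotingFeatureSelector(
        k=cfg["selection"]["k"], random_state=seed + 30
    )
    if cfg["selection"].get("scope", "train") == "train":
        selector.fit(X.iloc[tr], y[tr])
    else:
        selector.fit(X, y)

    ev = cfg["evaluation"]
    model_selector = IncrementalModelSelector(
        models=ev["models"],
        step=ev["step"],
        max_features=ev["max_features"],
        radius=ev["radius"],
        top_n=ev["top_n"],
        folds=ev["folds"],
        grid_density=ev["grid_density"],
        train_fraction=train_frac,
        random_state=split_seed,  # same seed => same split as FS saw
    )
    model_selector.fit(X, y, ranking=selector.ranking_)
    best = model_selector.best_

    # -- attributions on the held-out rows ---------------------------------
    feats = best.features
    X_bg = X.iloc[tr][feats]
    rows_key = cfg["explain"].get("rows", "test")
    X_rows = X.iloc[te][feats] if rows_key == "test" else X[feats]
    if best.coef is not None:
        explainer = LinearShapExplainer(model=best.estimator).fit(X_bg)
        shap = explainer.shap_values(X_rows)
    else:
        rng = np.random.default_rng(seed + 50)
        max_rows = int(cfg["explain"].get("max_rows", 50))
        if len(X_rows) > max_rows:
            keep = np.sort(rng.choice(len(X_rows), size=max_rows, replace=False))
            X_rows = X_rows.iloc[keep]
        margin = _margin_fn(best.estimator)
        bg = X_bg.to_numpy(dtype=float)
        if len(bg) > 100:
            bg = bg[np.sort(rng.choice(len(bg), size=100, replace=False))]
        n_perm = int(cfg["explain"].get("n_permutations", 100))
        values = np.vstack(
            [
                permutation_shap(margin, row, bg, n_permutations=n_perm,
                                 seed=seed + 60 + i)
                for i, row in enumerate(X_rows.to_numpy(dtype=float))
            ]
        )
        shap = ShapMatrix(
            values=values,
            base_value=float(np.mean(margin(bg))),
            background_mean=bg.mean(axis=0),
            feature_names=feats,
        )
    impact = rank_impact(shap)

    summary = {
        "seed": seed,
        "n_subjects": spec.n_subjects,
        "n_feature_columns": len(cohort.features.feature_names),
        "labeling": {
            "k": labeler.k_,
            "db_index_by_k": {str(k): v for k, v in labeler.db_index_by_k_.items()},
            "cluster_sizes": labeler.cluster_labels_.value_counts().sort_index().tolist(),
            "class_counts_balanced": [int((y == 0).sum()), int((y == 1).sum())],
        },
        "dropped_columns": list(prep.dropper_.dropped_columns_),
        "fs_winner": selector.winner_,
        "fs_cv_scores": selector.cv_scores_,
        "n_ranked_features": len(selector.ranking_),
        "best_model": {
            "model": best.model,
            "n_features": best.n_features,
            "accuracy": best.accuracy,
            "params": best.params,
        },
        "top_impact_features": impact.ranking_sum[:10],
    }

    result = PipelineResult(
        config=cfg, seed=seed, cohort=cohort, labeler=labeler, preprocessor=prep,
        selector=selector, model_selector=model_selector, shap=shap, impact=impact,
        summary=summary,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.labeler.labels_frame().to_csv(out / "labels.csv", index_label="subject_id")
    result.selector.ranking_frame().to_csv(out / "ranking.csv", index=False)
    result.model_selector.curves_frame().to_csv(out / "curves.csv", index=False)
    result.model_selector.best_.to_json(out / "best_model.json")
    result.shap.to_frame().to_csv(out / "shap_values.csv", index=False)
    result.impact.to_frame().to_csv(out / "impact.csv", index=False)
    (out / "report.json").write_text(json.dumps(result.summary, indent=1, sort_keys=True))
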