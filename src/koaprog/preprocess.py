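"""Baseline-table cleaning: sparse-column deletion, mode imputation,
min-max normalization.

The pipeline order is fixed — deletion, then imputation, then
normalization — and each transformer is an sklearn-style estimator
(``fit``/``transform``, fitted attributes with a trailing underscore) so
statistics are always estimated on training rows and applied unchanged to
held-out rows.  Held-out values falling outside the training min/max range
are clipped to [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable


def _as_frame(X) -> tuple[pd.DataFrame, CohortTable | None]:
    if isinstance(X, CohortTable):
        return X.data, X
    if isinstance(X, pd.DataFrame):
        return X, None
    raise TypeError("expected a CohortTable or a pandas DataFrame")


def _rewrap(frame: pd.DataFrame, table: CohortTable | None, step: str):
    if table is None:
        return frame
    out = CohortTable(
        data=frame,
        kinds={c: table.kinds[c] for c in frame.columns},
        categories={c: table.categories[c] for c in frame.columns},
        provenance=table.provenance + [step],
    )
    return out


class SparseColumnDropper(BaseEstimator, TransformerMixin):
    """Drop columns whose missing fraction strictly exceeds ``threshold``.

    A column is removed iff ``missing_count / n_subjects > threshold``
    (strict inequality: exactly 20 % missing survives the default 0.20
    threshold).  Surviving column order is preserved and the dropped ids
    are recorded in ``dropped_columns_``.
    """

    def __init__(self, threshold: float = 0.20):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must be in [0, 1)")
        frame, _ = _as_frame(X)
        if frame.empty:
            raise ValueError("empty table")
        frac = frame.isna().mean()
        self.dropped_columns_ = [c for c in frame.columns if frac[c] > self.threshold]
        self.kept_columns_ = [c for c in frame.columns if frac[c] <= self.threshold]
        return self

    def transform(self, X):
        frame, table = _as_frame(X)
        kept = [c for c in frame.columns if c not in set(self.dropped_columns_)]
        return _rewrap(frame[kept], table, "preprocess.drop_sparse_columns")


class ModeImputer(BaseEstimator, TransformerMixin):
    """Replace missing cells by the column mode over non-missing entries.

    Ties are broken deterministically by the smallest value (numeric) /
    lexicographically first level (categorical); pandas' ``mode`` returns
    candidates sorted, so the first is taken.
    """

    def fit(self, X, y=None):
        frame, _ = _as_frame(X)
        modes = {}
        for col in frame.columns:
            observed = frame[col].dropna()
            if observed.empty:
                raise ValueError(f"column {col!r} is entirely missing; cannot impute")
            modes[col] = observed.mode().iloc[0]
        self.modes_ = modes
        return self

    def transform(self, X):
        frame, table = _as_frame(X)
        out = frame.copy()
        for col in out.columns:
            if col in self.modes_:
                out[col] = out[col].fillna(self.modes_[col])
        return _rewrap(out, table, "preprocess.impute_most_frequent")


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Per-column affine map onto [0, 1]; constant columns map to zeros.

    Requires a fully imputed table (any missing cell is a pipeline-ordering
    violation and is rejected).  The fitted per-column ``min_``/``max_``
    are reused verbatim on held-out rows, whose transformed values are
    clipped to [0, 1].
    """

    def fit(self, X, y=None):
        frame, _ = _as_frame(X)
        self._check_complete(frame)
        self.min_ = frame.min()
        self.max_ = frame.max()
        return self

    def transform(self, X):
        frame, table = _as_frame(X)
        self._check_complete(frame)
        rng_ = (self.max_ - self.min_).replace(0, np.nan)
        out = (frame - self.min_) / rng_
        out = out.fillna(0.0).clip(0.0, 1.0)
        return _rewrap(out, table, "preprocess.minmax_normalize")

    @staticmethod
    def _check_complete(frame: pd.DataFrame) -> None:
        n = int(frame.isna().to_numpy().sum())
        if n:
            raise ValueError(
                f"normalization requires an imputed table; found {n} missing cells"
            )


class CohortPreprocessor(BaseEstimator, TransformerMixin):
    """Deletion -> imputation -> normalization as one leakage-safe transformer.

    ``fit`` estimates every statistic (missing fractions, modes, min/max)
    on the rows given to it; ``transform`` applies them unchanged, so test
    rows never influence the parameters.
    """

    def __init__(self, threshold: float = 0.20):
        self.threshold = threshold

    def fit(self, X, y=None):
        self.dropper_ = SparseColumnDropper(self.threshold).fit(X)
        dropped = self.dropper_.transform(X)
        self.imputer_ = ModeImputer().fit(dropped)
        imputed = self.imputer_.transform(dropped)
        self.normalizer_ = MinMaxNormalizer().fit(imputed)
        return self

    def transform(self, X):
        return self.normalizer_.transform(
            self.imputer_.transform(self.dropper_.transform(X))
        )

    # JSON sidecar with every fitted parameter, for audit/reuse
    def params_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "dropped_columns": list(self.dropper_.dropped_columns_),
            "modes": {k: _scalar(v) for k, v in self.imputer_.modes_.items()},
            "min": {k: float(v) for k, v in self.normalizer_.min_.items()},
            "max": {k: float(v) for k, v in self.normalizer_.max_.items()},
        }

    def save_params(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.params_dict(), indent=1, sort_keys=True))


def _scalar(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# --------------------------- thin functional API ---------------------------

def drop_sparse_columns(table, threshold: float = 0.20):
    """Drop columns with more than ``threshold`` missing; returns
    (table, dropped column ids)."""
    d = SparseColumnDropper(threshold).fit(table)
    return d.transform(table), list(d.dropped_columns_)


def impute_most_frequent(table):
    """Fill missing cells with each column's mode (smallest-value tie-break)."""
    return ModeImputer().fit(table).transform(table)


def minmax_normalize(table):
    """Map every column onto [0, 1]; constant columns become all-zero."""
    return MinMaxNormalizer().fit(table).transform(table)
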