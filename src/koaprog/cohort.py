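"""Tabular cohort container shared by every pipeline stage.

A :class:`CohortTable` is a subjects × features table together with the
declared schema (each column's feature *category* and *kind*) and a
provenance trail of the transformations applied to it.  The kind of a
column (``"numeric"`` or ``"categorical"``) always comes from the declared
schema — it is never inferred from the values, so integer-coded
categoricals cannot be silently misread as counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"
_KINDS = (NUMERIC, CATEGORICAL)


@dataclass
class CohortTable:
    """Subjects × features table with per-column category/kind tags.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject (index = subject id, unique), one column per
        feature.  Missing cells are NaN.  Categorical features are stored
        as small non-negative integer codes.
    kinds : dict
        Maps every column name to ``"numeric"`` or ``"categorical"``.
    categories : dict
        Maps every column name to its feature-category label
        (anthropometrics, nutrition, ...).
    provenance : list of str
        Ordered names of the transformations already applied.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    categories: dict[str, str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("subject ids must be unique")
        missing_tags = [c for c in self.data.columns if c not in self.kinds]
        if missing_tags:
            raise ValueError(f"columns without a kind tag: {missing_tags[:5]}")
        bad = {c: k for c, k in self.kinds.items() if k not in _KINDS}
        if bad:
            raise ValueError(f"invalid kind tags: {bad}")

    # -- convenience ------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            kinds=dict(self.kinds),
            categories=dict(self.categories),
            provenance=list(self.provenance),
        )

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing cells per column."""
        return self.data.isna().mean()

    # -- serialization ----------------------------------------------------
    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        """Write data as CSV (missing cells as empty fields) plus a JSON schema sidecar."""
        path = Path(path)
        self.data.to_csv(path, index_label="subject_id", na_rep="")
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema = {
            "kinds": self.kinds,
            "categories": self.categories,
            "provenance": self.provenance,
        }
        Path(schema_path).write_text(json.dumps(schema, indent=1, sort_keys=True))

    @classmethod
    def read_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "CohortTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        data = pd.read_csv(path, index_col="subject_id")
        schema = json.loads(Path(schema_path).read_text())
        return cls(
            data=data,
            kinds=schema["kinds"],
            categories=schema["categories"],
            provenance=schema.get("provenance", []),
        )

    def check_no_missing(self, context: str = "") -> None:
        n = int(self.data.isna().to_numpy().sum())
        if n:
            raise ValueError(f"{context}: table still contains {n} missing cells")

    def check_unit_interval(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("normalized table has cells outside [0, 1]")
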