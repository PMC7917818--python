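"""Synthetic knee-OA cohort generator.

Emulates the statistical structure the downstream pipeline assumes, so that
labeling, feature selection, model selection and explanation are all
testable without access-restricted registry data:

* per-subject, per-knee ordinal joint-space-narrowing (medial, "JSM")
  grade trajectories over five visits, with a minority of *progressors*
  whose grades increase over follow-up;
* a baseline feature table with the canonical nine-category allocation of
  725 candidate risk factors, a configurable number of planted
  class-informative features with a given standardized effect size, and a
  configurable mix of numeric and integer-coded categorical columns;
* completely-at-random per-column missingness whose rates straddle the
  20 % column-deletion threshold used during pre-processing.

A ground-truth record (:class:`CohortTruth`) is produced alongside every
cohort; downstream stages never read it — it exists only so tests can score
recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL, NUMERIC, CohortTable

#: Default per-category feature counts (totals 725).
DEFAULT_CATEGORY_ALLOCATION: dict[str, int] = {
    "anthropometrics": 37,
    "behavioral": 61,
    "symptoms": 108,
    "quality_of_life": 12,
    "medical_history": 123,
    "imaging_outcomes": 21,
    "nutrition": 224,
    "physical_exam": 115,
    "physical_activity": 24,
}

#: Ordinal grade scale for medial joint-space narrowing.
GRADE_LEVELS = (0, 1, 2, 3)

#: Marginal distribution of the constant grade of a non-progressing knee.
#: The grade marginals of real cohorts are not publicly characterized; this
#: is a documented free choice skewed toward low grades.
_BASE_GRADE_PROBS = np.array([0.55, 0.25, 0.12, 0.08])

#: Start-grade distribution of a progressing knee (must leave room to
#: worsen).  Weighted toward grade 2 so most progressors take the
#: clinically typical single-grade step over follow-up; multi-grade jumps
#: stay possible but rare.
_START_GRADE_PROBS = np.array([0.2, 0.2, 0.6])

#: Probability that a progressor progresses in (left, right, both) knees.
_PROGRESSING_KNEE_PROBS = np.array([0.45, 0.45, 0.10])

#: Category-code base probabilities for categorical features (4 levels).
_CAT_BASE_PROBS = np.array([0.4, 0.3, 0.2, 0.1])
_N_CAT_LEVELS = 4


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Cohort size.
    category_allocation : mapping
        Feature-category name -> number of columns.  The default reproduces
        the nine-category, 725-feature baseline table.
    progressor_prevalence : float
        Probability that a subject is a progressor (default 0.10, mirroring
        the strong imbalance between the stable and progressing clusters).
    n_informative : int
        Number of planted class-associated features.
    effect_size : float
        Standardized mean shift of informative numeric features between
        classes; also controls the category-probability tilt of informative
        categorical features.
    categorical_fraction : float
        Fraction of columns (per category) generated as integer-coded
        categoricals.
    missing_profile : mapping
        Missingness rate -> number of columns injected at that rate (rates
        chosen completely at random per cell).  The default plants columns
        both above and below the 0.20 deletion threshold.
    grade_noise_rate : float
        Per-visit probability of a ±1 grade flip (default 0 so labels are
        exactly recoverable).
    n_visits : int
        Number of visits per knee (>= 2).
    seed : int
        Master seed; the generator is bit-reproducible under a fixed spec.
    """

    n_subjects: int
    category_allocation: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_ALLOCATION)
    )
    progressor_prevalence: float = 0.10
    n_informative: int = 30
    effect_size: float = 0.8
    categorical_fraction: float = 0.3
    missing_profile: Mapping[float, int] = field(
        default_factory=lambda: {0.30: 10, 0.05: 20}
    )
    grade_noise_rate: float = 0.0
    n_visits: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.progressor_prevalence <= 1.0:
            raise ValueError("progressor_prevalence must be in [0, 1]")
        if not 0.0 <= self.categorical_fraction <= 1.0:
            raise ValueError("categorical_fraction must be in [0, 1]")
        if not 0.0 <= self.grade_noise_rate <= 1.0:
            raise ValueError("grade_noise_rate must be in [0, 1]")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if any(v < 0 for v in self.category_allocation.values()):
            raise ValueError("category counts must be non-negative")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds the feature "
                f"budget ({self.n_features})"
            )
        for rate in self.missing_profile:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate {rate} outside [0, 1]")

    @property
    def n_features(self) -> int:
        return int(sum(self.category_allocation.values()))


@dataclass
class CohortTruth:
    """Ground truth written alongside a generated cohort (never read back
    by any analysis stage)."""

    progressor_flags: np.ndarray
    informative_ids: list[str]
    generator_params: dict
    injected_missing: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "progressor_flags": [int(v) for v in self.progressor_flags],
            "informative_ids": list(self.informative_ids),
            "generator_params": _jsonable(self.generator_params),
            "injected_missing": self.injected_missing,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            progressor_flags=np.asarray(payload["progressor_flags"], dtype=int),
            informative_ids=list(payload["informative_ids"]),
            generator_params=payload["generator_params"],
            injected_missing=payload.get("injected_missing", {}),
        )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def generate_trajectories(
    n_subjects: int,
    prevalence: float = 0.10,
    grade_noise_rate: float = 0.0,
    seed: int = 0,
    n_visits: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-subject left/right knee grade trajectories.

    Non-progressors receive a constant grade in both knees.  Progressors
    receive, in at least one knee, a monotone non-decreasing trajectory
    whose total increase is >= 1 grade; the other knee may stay constant.
    With ``grade_noise_rate > 0`` single visits are flipped by ±1 (clipped
    to the grade scale) to exercise robustness; the default is 0 so the
    progression statistic separates the classes exactly.

    Returns
    -------
    trajectories : DataFrame
        Index = subject id; columns ``left_v1..left_vn, right_v1..right_vn``.
    flags : ndarray of int
        1 for progressors, 0 otherwise.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    if not 0.0 <= grade_noise_rate <= 1.0:
        raise ValueError("grade_noise_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    flags = (rng.random(n_subjects) < prevalence).astype(int)
    grades = np.empty((n_subjects, 2, n_visits), dtype=int)

    for i in range(n_subjects):
        if flags[i]:
            # which knee(s) progress: left / right / both
            which = rng.choice(3, p=_PROGRESSING_KNEE_PROBS)
            progressing = {0: (True, False), 1: (False, True), 2: (True, True)}[which]
            for knee in (0, 1):
                if progressing[knee]:
                    grades[i, knee] = _progressing_trajectory(rng, n_visits)
                else:
                    grades[i, knee] = _constant_trajectory(rng, n_visits)
        else:
            for knee in (0, 1):
                grades[i, knee] = _constant_trajectory(rng, n_visits)

    if grade_noise_rate > 0:
        flips = rng.random(grades.shape) < grade_noise_rate
        signs = rng.choice((-1, 1), size=grades.shape)
        grades = np.clip(grades + flips * signs, GRADE_LEVELS[0], GRADE_LEVELS[-1])

    cols = [f"left_v{j + 1}" for j in range(n_visits)] + [
        f"right_v{j + 1}" for j in range(n_visits)
    ]
    data = np.concatenate([grades[:, 0, :], grades[:, 1, :]], axis=1)
    index = pd.Index([f"S{i:05d}" for i in range(n_subjects)], name="subject_id")
    return pd.DataFrame(data, index=index, columns=cols), flags


def _constant_trajectory(rng: np.random.Generator, n_visits: int) -> np.ndarray:
    g = rng.choice(len(_BASE_GRADE_PROBS), p=_BASE_GRADE_PROBS)
    return np.full(n_visits, g, dtype=int)


def _progressing_trajectory(rng: np.random.Generator, n_visits: int) -> np.ndarray:
    start = rng.choice(len(_START_GRADE_PROBS), p=_START_GRADE_PROBS)
    total = rng.integers(1, GRADE_LEVELS[-1] - start + 1)  # >= 1, stays on scale
    # distribute `total` unit increments over the n_visits - 1 gaps
    gaps = rng.choice(n_visits - 1, size=total, replace=True)
    increments = np.bincount(gaps, minlength=n_visits - 1)
    return start + np.concatenate([[0], np.cumsum(increments)])


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def generate_feature_table(
    spec: CohortSpec,
    progressor_flags: np.ndarray,
    seed: int | None = None,
) -> tuple[CohortTable, CohortTruth]:
    """Generate the baseline feature table with planted informative columns.

    Informative numeric features are ``x = effect_size * z + eps`` with
    ``eps ~ N(0, 1)`` and ``z`` the progressor flag; informative
    categorical features use class-tilted category probabilities.  All
    other features are independent of the class.  Every column carries a
    category tag and a kind tag.
    """
    flags = np.asarray(progressor_flags, dtype=int)
    if len(flags) != spec.n_subjects:
        raise ValueError("progressor_flags length must equal spec.n_subjects")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    names: list[str] = []
    kinds: dict[str, str] = {}
    categories: dict[str, str] = {}
    for cat, count in spec.category_allocation.items():
        n_categorical = int(round(spec.categorical_fraction * count))
        for j in range(count):
            name = f"{cat}_{j:03d}"
            names.append(name)
            kinds[name] = CATEGORICAL if j < n_categorical else NUMERIC
            categories[name] = cat

    informative = (
        sorted(rng.choice(names, size=spec.n_informative, replace=False).tolist())
        if spec.n_informative
        else []
    )
    informative_set = set(informative)

    n = spec.n_subjects
    z = flags.astype(float)
    columns: dict[str, np.ndarray] = {}
    tilt = np.exp(spec.effect_size * np.arange(_N_CAT_LEVELS))
    p_shift = _CAT_BASE_PROBS * tilt
    p_shift = p_shift / p_shift.sum()
    for name in names:
        if kinds[name] == NUMERIC:
            x = rng.standard_normal(n)
            if name in informative_set:
                x = x + spec.effect_size * z
            columns[name] = x
        else:
            if name in informative_set:
                codes = np.where(
                    flags == 1,
                    rng.choice(_N_CAT_LEVELS, size=n, p=p_shift),
                    rng.choice(_N_CAT_LEVELS, size=n, p=_CAT_BASE_PROBS),
                )
            else:
                codes = rng.choice(_N_CAT_LEVELS, size=n, p=_CAT_BASE_PROBS)
            columns[name] = codes.astype(float)

    index = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    table = CohortTable(
        data=pd.DataFrame(columns, index=index)[names],
        kinds=kinds,
        categories=categories,
        provenance=["synthdata.generate_feature_table"],
    )
    truth = CohortTruth(
        progressor_flags=flags,
        informative_ids=informative,
        generator_params=asdict(spec),
    )
    return table, truth


def inject_missingness(
    table: CohortTable,
    per_column_rates: Mapping[str, float],
    seed: int = 0,
) -> tuple[CohortTable, dict[str, int]]:
    """Blank cells completely at random, per column, at the given rates.

    Returns the new table and the realized per-column missing counts so the
    injection is re-checkable.
    """
    for col, rate in per_column_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        if col not in table.data.columns:
            raise KeyError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    counts: dict[str, int] = {}
    for col, rate in per_column_rates.items():
        if rate == 0.0:
            continue
        mask = rng.random(len(out.data)) < rate
        out.data.loc[mask, col] = np.nan
        counts[col] = int(mask.sum())
    out.provenance.append("synthdata.inject_missingness")
    return out, counts


# ---------------------------------------------------------------------------
# One-call cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    features: CohortTable
    trajectories: pd.DataFrame
    truth: CohortTruth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Trajectories + feature table + missingness, all from ``spec.seed``."""
    trajectories, flags = generate_trajectories(
        spec.n_subjects,
        prevalence=spec.progressor_prevalence,
        grade_noise_rate=spec.grade_noise_rate,
        seed=spec.seed,
        n_visits=spec.n_visits,
    )
    table, truth = generate_feature_table(spec, flags)

    # pick the columns to degrade among non-informative ones so planted
    # signal and the deletion rule do not interact
    rng = np.random.default_rng(spec.seed + 2)
    eligible = [c for c in table.feature_names if c not in set(truth.informative_ids)]
    rates: dict[str, float] = {}
    cursor = 0
    order = rng.permutation(eligible)
    for rate, n_cols in spec.missing_profile.items():
        for col in order[cursor : cursor + n_cols]:
            rates[str(col)] = float(rate)
        cursor += n_cols
    if rates:
        table, counts = inject_missingness(table, rates, seed=spec.seed + 3)
        truth.injected_missing = counts
    return SyntheticCohort(features=table, trajectories=trajectories, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write feature CSV (+schema), trajectory CSV, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "trajectories": out / "trajectories.csv",
        "truth": out / "truth.json",
    }
    cohort.features.to_csv(paths["features"])
    cohort.trajectories.to_csv(paths["trajectories"], index_label="subject_id")
    cohort.truth.to_json(paths["truth"])
    return paths
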