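"""Progression phenotyping from ordinal joint-space-narrowing trajectories.

For each knee the progression statistic is the sum of absolute consecutive
grade differences,

    score = sum_{k=2..n} | m_k - m_{k-1} |,

and the combined (both-knees) statistic is the sum of the left and right
scores.  A score of 0 is equivalent to a constant trajectory.  Subjects
are then clustered on this one-dimensional statistic (k-means or k-medoids
with city-block distance and 5 replicates, or agglomerative clustering
with Chebyshev distance and complete linkage), the cluster count is chosen
by the Davies-Bouldin index, the two-cluster solution is binarized (the
lower-mean cluster is the non-progressor class) and the majority class is
randomly undersampled to the minority size.

The city-block k-means/k-medoids here are deliberately bespoke: centers
are per-cluster medians (the L1 centroid) / medoid data points, which is
not what a squared-error k-means computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

# ---------------------------------------------------------------------------
# Progression statistic
# ---------------------------------------------------------------------------


@dataclass
class KneeScore:
    """Per-knee progression fragment: consecutive diffs and their |.| sum."""

    diffs: np.ndarray
    score: float


def knee_score(grades) -> KneeScore:
    """Sum of absolute consecutive differences of one knee's grade series."""
    m = np.asarray(grades, dtype=float)
    if m.ndim != 1 or len(m) < 2:
        raise ValueError("a trajectory needs at least 2 visits")
    if not np.all(np.isfinite(m)):
        raise ValueError("trajectory contains non-finite grades")
    diffs = np.diff(m)
    return KneeScore(diffs=diffs, score=float(np.abs(diffs).sum()))


def combined_score(left, right) -> float:
    """Left-knee score plus right-knee score (both-knees strategy)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) != len(right):
        raise ValueError("left and right trajectories must have equal visit counts")
    return knee_score(left).score + knee_score(right).score


def score_trajectories(trajectories: pd.DataFrame, strategy: str = "combined") -> pd.Series:
    """Per-subject progression score from a left_v*/right_v* trajectory table.

    Subjects with any missing visit are excluded (imputing ordinal grades
    would fabricate progression).
    """
    if strategy not in ("left", "right", "combined"):
        raise ValueError(f"unknown strategy {strategy!r}")
    left_cols = sorted(
        (c for c in trajectories.columns if c.startswith("left_v")),
        key=lambda c: int(c.split("_v")[1]),
    )
    right_cols = sorted(
        (c for c in trajectories.columns if c.startswith("right_v")),
        key=lambda c: int(c.split("_v")[1]),
    )
    if strategy in ("left", "combined") and len(left_cols) < 2:
        raise ValueError("need at least 2 left-knee visits")
    if strategy in ("right", "combined") and len(right_cols) < 2:
        raise ValueError("need at least 2 right-knee visits")

    needed = {"left": left_cols, "right": right_cols, "combined": left_cols + right_cols}[
        strategy
    ]
    complete = trajectories[needed].notna().all(axis=1)
    sub = trajectories.loc[complete, needed].to_numpy(dtype=float)

    if strategy == "combined":
        nl = len(left_cols)
        scores = np.abs(np.diff(sub[:, :nl], axis=1)).sum(axis=1) + np.abs(
            np.diff(sub[:, nl:], axis=1)
        ).sum(axis=1)
    else:
        scores = np.abs(np.diff(sub, axis=1)).sum(axis=1)
    return pd.Series(scores, index=trajectories.index[complete], name="score")


# ---------------------------------------------------------------------------
# 1-D clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    method: str
    k: int
    labels: np.ndarray  # values in 1..k
    centers: np.ndarray  # ascending representative score per cluster
    objective: float  # total within-cluster city-block cost
    replicate_costs: list[float] = field(default_factory=list)
    db_index_by_k: dict[int, float] = field(default_factory=dict)


def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # nearest center by |x - c|; ties go to the lower-index (smaller) center
    return np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)


def _l1_cost(x: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(np.abs(x - centers[assign]).sum())


def _lower_median(v: np.ndarray) -> float:
    s = np.sort(v)
    return float(s[(len(s) - 1) // 2])


def _lloyd(x, k, rng, center_fn, max_iter=300):
    """One Lloyd replicate: random distinct-value init, assign/update loop."""
    distinct = np.unique(x)
    centers = np.sort(rng.choice(distinct, size=k, replace=False)).astype(float)
    for _ in range(max_iter):
        assign = _assign(x, centers)
        if len(np.unique(assign)) < k:
            return None  # empty cluster: caller re-initializes
        new = np.sort(np.array([center_fn(x[assign == j]) for j in range(k)]))
        if np.array_equal(new, centers):
            break
        centers = new
    assign = _assign(x, centers)
    if len(np.unique(assign)) < k:
        return None
    return centers, assign


def _range_cost(xs, s, e, center_fn):
    c = center_fn(xs[s:e])
    return float(np.abs(xs[s:e] - c).sum()), float(c)


def _refine_boundaries(xs, cuts, center_fn):
    """Hill-climb the value-contiguous partition of sorted data ``xs``.

    ``cuts`` are the k-1 internal split indices.  In 1-D the city-block
    optimum is contiguous in value, so moving blocks of equal values
    across adjacent boundaries while the total cost decreases escapes the
    shallow local optima Lloyd iterations are prone to.
    """
    bounds = [0] + list(cuts) + [len(xs)]
    improved = True
    while improved:
        improved = False
        for b in range(1, len(bounds) - 1):
            s, m, e = bounds[b - 1], bounds[b], bounds[b + 1]
            base = _range_cost(xs, s, m, center_fn)[0] + _range_cost(xs, m, e, center_fn)[0]
            best_m, best_cost = m, base
            # move the value-block left of the cut into the right cluster
            left_val = xs[m - 1]
            nm = np.searchsorted(xs[s:m], left_val) + s
            if nm > s:
                cost = _range_cost(xs, s, nm, center_fn)[0] + _range_cost(xs, nm, e, center_fn)[0]
                if cost < best_cost - 1e-12:
                    best_m, best_cost = nm, cost
            # move the value-block right of the cut into the left cluster
            right_val = xs[m]
            nm = np.searchsorted(xs[m:e], right_val, side="right") + m
            if nm < e:
                cost = _range_cost(xs, s, nm, center_fn)[0] + _range_cost(xs, nm, e, center_fn)[0]
                if cost < best_cost - 1e-12:
                    best_m, best_cost = nm, cost
            if best_m != m:
                bounds[b] = best_m
                improved = True
    return bounds[1:-1]


def _replicate(x, k, rng, center_fn):
    res = _lloyd(x, k, rng, center_fn)
    if res is None:
        return None
    centers, assign = res
    # contiguous-in-value partition -> refine cluster boundaries
    order = np.argsort(x, kind="stable")
    xs = x[order]
    sizes = np.bincount(assign, minlength=k)
    cuts = np.cumsum(sizes)[:-1]
    cuts = _refine_boundaries(xs, cuts, center_fn)
    bounds = [0] + list(cuts) + [len(xs)]
    centers = np.array(
        [_range_cost(xs, bounds[j], bounds[j + 1], center_fn)[1] for j in range(k)]
    )
    labels_sorted = np.repeat(np.arange(k), np.diff(bounds))
    assign = np.empty(len(x), dtype=int)
    assign[order] = labels_sorted
    return centers, assign, _l1_cost(x, centers, assign)


def _kmeans_once(x, k, rng):
    return _replicate(x, k, rng, np.median)


def _kmedoids_once(x, k, rng):
    return _replicate(x, k, rng, _lower_median)


def cluster_scores(
    scores,
    method: str = "kmeans",
    k: int = 2,
    n_replicates: int = 5,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster 1-D progression scores into ``k`` groups.

    k-means / k-medoids use city-block distance with ``n_replicates``
    seeded restarts (best replicate by total within-cluster cost);
    hierarchical uses a Chebyshev-distance agglomerative tree with
    complete linkage, cut at ``k``.  Labels are 1..k ordered by ascending
    cluster representative.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("scores must be a non-empty 1-D sequence")
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x)
    if k > len(distinct):
        raise ValueError(
            f"k={k} exceeds the number of distinct score values ({len(distinct)})"
        )
    if method not in ("kmeans", "kmedoids", "hierarchical"):
        raise ValueError(f"unknown clustering method {method!r}")

    if k == 1:
        center = np.array([np.median(x)])
        assign = np.zeros(len(x), dtype=int)
        return ClusteringResult(
            method, 1, assign + 1, center, _l1_cost(x, center, assign)
        )

    if method == "hierarchical":
        Z = linkage(x[:, None], method="complete", metric="chebyshev")
        raw = fcluster(Z, t=k, criterion="maxclust")
        centers = np.array([np.median(x[raw == c]) for c in np.unique(raw)])
        order = np.argsort(centers, kind="stable")
        relabel = {c: r for r, c in zip(np.argsort(order), np.unique(raw))}
        assign = np.array([relabel[c] for c in raw])
        centers = centers[order]
        return ClusteringResult(
            method, k, assign + 1, centers, _l1_cost(x, centers, assign)
        )

    once = _kmeans_once if method == "kmeans" else _kmedoids_once
    rng = np.random.default_rng(seed)
    best = None
    costs: list[float] = []
    for _ in range(n_replicates):
        result = None
        for _attempt in range(20):  # re-initialize on empty clusters
            result = once(x, k, rng)
            if result is not None:
                break
        if result is None:
            continue
        centers, assign, cost = result
        costs.append(cost)
        if best is None or cost < best[2]:
            best = (centers, assign, cost)
    if best is None:
        raise RuntimeError("all clustering replicates produced empty clusters")
    centers, assign, cost = best
    return ClusteringResult(method, k, assign + 1, centers, cost, replicate_costs=costs)


# ---------------------------------------------------------------------------
# Davies-Bouldin model selection
# ---------------------------------------------------------------------------


def davies_bouldin(scores, labels) -> float:
    """Davies-Bouldin index with mean centroids and Euclidean distances.

    DB = (1/k) * sum_i max_{j != i} (S_i + S_j) / M_ij, where S_i is the
    mean distance of cluster i's members to its centroid and M_ij the
    distance between centroids.  Lower is better; 0 iff all clusters have
    zero scatter.  Coincident centroids are rejected.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    cents = np.array([x[labels == c].mean() for c in uniq])
    scatter = np.array([np.abs(x[labels == c] - m).mean() for c, m in zip(uniq, cents)])
    k = len(uniq)
    db = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            m = abs(cents[i] - cents[j])
            if m == 0:
                raise ValueError(
                    f"coincident centroids for clusters {uniq[i]} and {uniq[j]}"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / m)
        db += worst
    return db / k


def select_k(
    scores,
    method: str = "kmeans",
    k_range=range(2, 7),
    n_replicates: int = 5,
    seed: int = 0,
    force_k: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count minimizing the Davies-Bouldin index.

    Scans ``k_range`` (clipped to the number of distinct score values);
    any k whose index is undefined on this data (coincident centroids) is
    recorded as NaN and skipped.  Ties go to the smallest k.  ``force_k``
    overrides the scan while still reporting the profile.
    """
    x = np.asarray(scores, dtype=float)
    distinct = len(np.unique(x))
    profile: dict[int, float] = {}
    for k in k_range:
        if k < 2 or k > distinct:
            continue
        try:
            res = cluster_scores(x, method=method, k=k, n_replicates=n_replicates, seed=seed)
            profile[k] = davies_bouldin(x, res.labels)
        except (ValueError, RuntimeError):
            profile[k] = float("nan")
    if force_k is not None:
        return int(force_k), profile
    valid = {k: v for k, v in profile.items() if np.isfinite(v)}
    if not valid:
        raise ValueError("no valid cluster count in the scanned range")
    best = min(valid, key=lambda k: (valid[k], k))
    return best, profile


# ---------------------------------------------------------------------------
# Binarization and rebalancing
# ---------------------------------------------------------------------------


def binarize(result: ClusteringResult, scores) -> np.ndarray:
    """Map a 2-cluster solution to classes: lower-mean cluster -> 0."""
    if result.k != 2:
        raise ValueError("binarization is defined for k = 2 only")
    x = np.asarray(scores, dtype=float)
    means = np.array([x[result.labels == c].mean() for c in (1, 2)])
    if means[0] == means[1]:
        raise ValueError("degenerate clustering: equal cluster means")
    low = 1 if means[0] < means[1] else 2
    return (result.labels != low).astype(int)


def undersample(subject_ids, classes, seed: int = 0) -> list:
    """Reduce the majority class to the minority size, uniformly at random.

    Returns the kept subject ids in their original order.
    """
    ids = np.asarray(subject_ids)
    classes = np.asarray(classes)
    if len(ids) != len(classes):
        raise ValueError("subject_ids and classes must align")
    counts = {c: int((classes == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be non-empty")
    minority = min(counts, key=counts.get)
    majority = 1 - minority
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(classes == majority)
    keep_maj = rng.choice(maj_idx, size=counts[minority], replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(classes == minority), keep_maj]))
    return list(ids[keep])


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class ProgressionLabeler(BaseEstimator):
    """Trajectory table -> balanced binary progression labels.

    Parameters
    ----------
    strategy : {"combined", "left", "right"}
        Which progression statistic to cluster: one knee's score or the
        two-knee sum.
    method : {"kmeans", "kmedoids", "hierarchical"}
    k : "auto" or int
        "auto" scans ``k_range`` with the Davies-Bouldin index; an integer
        forces the cluster count (the adopted setting for binary phenotyping is 2).
    balance : bool
        Whether to undersample the majority class after binarization.

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : pandas.Series — per-subject progression score.
    k_, db_index_by_k_ : chosen cluster count and DB profile.
    cluster_labels_ : pandas.Series in 1..k.
    classes_ : pandas.Series of 0/1 (requires the 2-cluster solution).
    balanced_ids_ : subject ids kept after undersampling.
    """

    def __init__(
        self,
        strategy: str = "combined",
        method: str = "kmeans",
        k="auto",
        k_range: tuple[int, int] = (2, 6),
        n_replicates: int = 5,
        balance: bool = True,
        random_state: int = 0,
    ):
        self.strategy = strategy
        self.method = method
        self.k = k
        self.k_range = k_range
        self.n_replicates = n_replicates
        self.balance = balance
        self.random_state = random_state

    def fit(self, trajectories: pd.DataFrame, y=None):
        self.scores_ = score_trajectories(trajectories, strategy=self.strategy)
        self.excluded_ids_ = [
            s for s in trajectories.index if s not in self.scores_.index
        ]
        x = self.scores_.to_numpy()
        scan = range(self.k_range[0], self.k_range[1] + 1)
        force = None if self.k == "auto" else int(self.k)
        self.k_, self.db_index_by_k_ = select_k(
            x,
            method=self.method,
            k_range=scan,
            n_replicates=self.n_replicates,
            seed=self.random_state,
            force_k=force,
        )
        self.clustering_ = cluster_scores(
            x,
            method=self.method,
            k=self.k_,
            n_replicates=self.n_replicates,
            seed=self.random_state,
        )
        self.clustering_.db_index_by_k = self.db_index_by_k_
        self.cluster_labels_ = pd.Series(
            self.clustering_.labels, index=self.scores_.index, name="cluster"
        )
        if self.k_ == 2:
            classes = binarize(self.clustering_, x)
            self.classes_ = pd.Series(classes, index=self.scores_.index, name="class")
            if self.balance:
                self.balanced_ids_ = undersample(
                    self.scores_.index.to_numpy(), classes, seed=self.random_state
                )
            else:
                self.balanced_ids_ = list(self.scores_.index)
        else:
            self.classes_ = None
            self.balanced_ids_ = None
        return self

    def fit_predict(self, trajectories: pd.DataFrame, y=None) -> pd.Series:
        self.fit(trajectories)
        if self.classes_ is None:
            raise ValueError(
                f"binary labels undefined for k={self.k_}; refit with k=2"
            )
        return self.classes_

    def labels_frame(self) -> pd.DataFrame:
        """Per-subject score, cluster, class and kept-after-balancing flag."""
        out = pd.DataFrame(
            {"score": self.scores_, "cluster": self.cluster_labels_}
        )
        if self.classes_ is not None:
            out["class"] = self.classes_
            kept = set(self.balanced_ids_)
            out["kept"] = [int(s in kept) for s in out.index]
        return out
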