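"""Independent brute-force oracles used by the clustering tests."""

import numpy as np


def brute_force_two_partition_cost(x) -> float:
    """Optimal total city-block cost over all threshold 2-partitions of
    sorted 1-D data, each side centered at its median.

    The 1-D city-block optimum is contiguous in sorted order, so
    enumerating every split point is exhaustive.
    """
    xs = np.sort(np.asarray(x, dtype=float))
    best = np.inf
    for t in range(1, len(xs)):
        left, right = xs[:t], xs[t:]
        cost = np.abs(left - np.median(left)).sum() + np.abs(
            right - np.median(right)
        ).sum()
        best = min(best, cost)
    return float(best)


def score_fixture_battery(n_sets: int = 200, seed: int = 0):
    """Small 1-D score sets (<= 12 points, >= 2 distinct values): integer
    grades, Gaussian, and well-separated bimodal shapes."""
    rng = np.random.default_rng(seed)
    sets = []
    while len(sets) < n_sets:
        n = int(rng.integers(4, 13))
        kind = len(sets) % 3
        if kind == 0:
            x = rng.integers(0, 5, size=n).astype(float)
        elif kind == 1:
            x = rng.normal(0.0, 1.0, size=n)
        else:
            x = np.concatenate(
                [rng.normal(0, 0.1, size=n // 2), rng.normal(5, 0.1, size=n - n // 2)]
            )
        if len(np.unique(x)) >= 2:
            sets.append(x)
    return sets
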