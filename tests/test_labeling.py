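import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import davies_bouldin_score as sk_db

from oracle_utils import brute_force_two_partition_cost, score_fixture_battery

from koaprog.labeling import (
    ClusteringResult,
    ProgressionLabeler,
    binarize,
    cluster_scores,
    combined_score,
    davies_bouldin,
    knee_score,
    score_trajectories,
    select_k,
    undersample,
)
from koaprog.synthdata import CohortSpec, generate_cohort


class TestProgressionStatistic:
    @pytest.mark.parametrize(
        "grades, expected",
        [
            ([2, 2, 2, 2, 2], 0.0),
            ([0, 1, 1, 2, 3], 3.0),
            ([3, 2, 2, 1, 1], 2.0),
        ],
    )
    def test_worked_examples(self, grades, expected):
        assert knee_score(grades).score == expected

    def test_diffs_are_consecutive_differences(self):
        assert knee_score([0, 1, 1, 2, 3]).diffs.tolist() == [1, 0, 1, 1]

    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ([0, 1, 1, 2, 3], [1, 1, 1, 1, 1], 3.0),
            ([2, 2, 2], [3, 3, 3], 0.0),
            ([0, 1, 1, 1, 1], [1, 1, 2, 2, 3], 3.0),  # 1 + 2
        ],
    )
    def test_combined_is_sum_of_knee_scores(self, left, right, expected):
        assert combined_score(left, right) == expected

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValueError):
            knee_score([1])

    def test_mismatched_visit_counts_rejected(self):
        with pytest.raises(ValueError):
            combined_score([0, 1, 2], [0, 1])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=8))
    def test_reversal_invariance(self, grades):
        assert knee_score(grades).score == knee_score(grades[::-1]).score

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=8))
    def test_zero_iff_constant(self, grades):
        assert (knee_score(grades).score == 0) == (len(set(grades)) == 1)

    def test_missing_visit_subjects_excluded(self):
        traj = pd.DataFrame(
            {
                "left_v1": [0, 0], "left_v2": [0, np.nan],
                "right_v1": [0, 0], "right_v2": [1, 0],
            },
            index=["A", "B"],
        )
        scores = score_trajectories(traj, "combined")
        assert list(scores.index) == ["A"]
        assert scores["A"] == 1.0


class TestClusterScores:
    def test_worked_two_cluster_partition(self):
        res = cluster_scores([0, 0.1, 0.2, 5.0, 5.1], "kmeans", k=2, seed=0)
        assert res.labels.tolist() == [1, 1, 1, 2, 2]
        assert res.centers.tolist() == [0.1, 5.05]

    def test_single_cluster_degenerate(self):
        res = cluster_scores([1.0, 2.0, 3.0], "kmeans", k=1)
        assert (res.labels == 1).all()

    def test_k_equals_n_zero_objective(self):
        res = cluster_scores([1.0, 2.0, 4.0, 8.0], "kmeans", k=4, seed=0)
        assert res.objective == 0.0
        assert sorted(res.labels) == [1, 2, 3, 4]

    def test_k_above_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            cluster_scores([0.0, 0.0, 1.0], "kmeans", k=3)

    @pytest.mark.parametrize("method", ["kmeans", "kmedoids"])
    def test_matches_brute_force_on_small_sets(self, method):
        for i, x in enumerate(score_fixture_battery(60, seed=3)):
            res = cluster_scores(x, method=method, k=2, n_replicates=5, seed=i)
            assert res.objective <= brute_force_two_partition_cost(x) + 1e-9

    def test_kmedoids_centers_are_data_points(self):
        x = np.array([0.0, 0.3, 0.9, 5.0, 6.0, 7.5])
        res = cluster_scores(x, "kmedoids", k=2, seed=1)
        assert all(c in x for c in res.centers)

    def test_hierarchical_partitions_separated_data(self):
        x = np.concatenate([np.zeros(10), np.full(5, 8.0) + 0.01 * np.arange(5)])
        res = cluster_scores(x, "hierarchical", k=2)
        assert (res.labels[:10] == 1).all() and (res.labels[10:] == 2).all()


class TestDaviesBouldin:
    def test_zero_scatter_gives_zero(self):
        assert davies_bouldin([0, 0, 10, 10], [1, 1, 2, 2]) == 0.0

    def test_hand_computed_quarter(self):
        assert davies_bouldin([1, 3, 9, 11], [1, 1, 2, 2]) == pytest.approx(0.25)

    def test_wrong_merge_scores_worse_than_truth(self):
        x = np.concatenate([np.arange(5), 10 + np.arange(5), 20 + np.arange(5)])
        true = np.repeat([1, 2, 3], 5)
        # merge the first two clusters, split the third
        wrong = np.concatenate([np.repeat(1, 10), [2, 2, 2, 3, 3]])
        assert davies_bouldin(x, wrong) > davies_bouldin(x, true)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin([0, 2, 0, 2], [1, 1, 2, 2])

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            labels = rng.integers(1, 4, size=30)
            if len(np.unique(labels)) < 2:
                continue
            ours = davies_bouldin(x, labels)
            theirs = sk_db(x[:, None], labels)
            assert ours == pytest.approx(theirs, rel=1e-9)


class TestSelectK:
    def test_bimodal_sample_selects_two(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.5, 500), rng.normal(8, 0.5, 60)])
        k, profile = select_k(x, "kmeans", seed=1)
        assert k == 2
        assert set(profile) == {2, 3, 4, 5, 6}

    def test_three_separated_masses_select_three(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(0, 0.3, 80), rng.normal(5, 0.3, 80), rng.normal(10, 0.3, 80)]
        )
        k, _ = select_k(x, "kmeans", seed=1)
        assert k == 3

    def test_force_k_overrides_profile(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(0, 0.3, 80), rng.normal(5, 0.3, 80), rng.normal(10, 0.3, 80)]
        )
        k, _ = select_k(x, "kmeans", seed=1, force_k=2)
        assert k == 2


class TestBinarizeAndBalance:
    def test_lower_mean_cluster_is_class_zero(self):
        x = np.array([0.1, 0.2, 4.0, 5.0])
        res = cluster_scores(x, "kmeans", k=2, seed=0)
        classes = binarize(res, x)
        assert classes.tolist() == [0, 0, 1, 1]

    def test_equal_means_rejected(self):
        res = ClusteringResult(
            method="kmeans", k=2, labels=np.array([1, 2, 1, 2]),
            centers=np.array([0.5, 0.5]), objective=0.0,
        )
        with pytest.raises(ValueError, match="equal"):
            binarize(res, np.array([0.0, 1.0, 1.0, 0.0]))

    def test_k_not_two_rejected(self):
        res = cluster_scores([0.0, 1.0, 5.0], "kmeans", k=3, seed=0)
        with pytest.raises(ValueError):
            binarize(res, np.array([0.0, 1.0, 5.0]))

    def test_undersample_sizes_and_determinism(self):
        ids = np.array([f"S{i}" for i in range(130)])
        classes = np.array([0] * 100 + [1] * 30)
        kept = undersample(ids, classes, seed=4)
        kept_classes = classes[np.isin(ids, kept)]
        assert (kept_classes == 0).sum() == 30 and (kept_classes == 1).sum() == 30
        assert kept == undersample(ids, classes, seed=4)

    def test_balanced_input_unchanged(self):
        ids = np.arange(10)
        classes = np.array([0, 1] * 5)
        assert sorted(undersample(ids, classes, seed=0)) == sorted(ids)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            undersample(np.arange(4), np.zeros(4, dtype=int))


class TestProgressionLabeler:
    def test_noiseless_recovery_matches_truth(self):
        cohort = generate_cohort(
            CohortSpec(n_subjects=1500, category_allocation={"a": 5}, n_informative=0,
                       missing_profile={}, seed=31)
        )
        lab = ProgressionLabeler(strategy="combined", k=2, random_state=1).fit(
            cohort.trajectories
        )
        assert np.array_equal(
            lab.classes_.to_numpy(), cohort.truth.progressor_flags
        )
        kept = lab.classes_.loc[lab.balanced_ids_]
        assert (kept == 0).sum() == (kept == 1).sum()

    def test_per_knee_strategies_run(self):
        cohort = generate_cohort(
            CohortSpec(n_subjects=400, category_allocation={"a": 5}, n_informative=0,
                       missing_profile={}, seed=32)
        )
        for strategy in ("left", "right"):
            lab = ProgressionLabeler(strategy=strategy, k=2, random_state=1).fit(
                cohort.trajectories
            )
            # a knee-specific progressor set is a subset of the combined one
            assert set(lab.classes_[lab.classes_ == 1].index) <= set(
                np.array([f"S{i:05d}" for i in range(400)])[
                    cohort.truth.progressor_flags == 1
                ]
            )
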