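import numpy as np
import pandas as pd
import pytest

from koaprog.fsvote import (
    TECHNIQUES,
    FsResult,
    VotingFeatureSelector,
    embedded_importance,
    filter_scores,
    rfe_rank,
    select_top,
    technique_cv_score,
    vote_rank,
)


def _planted(n=400, noise=9, effect=1.5, seed=0):
    """One informative column (standardized shift = effect) among noise."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    cols = {f"noise{i}": rng.random(n) for i in range(noise)}
    s = effect * y + rng.standard_normal(n)
    cols["signal"] = (s - s.min()) / (s.max() - s.min())
    X = pd.DataFrame(cols)[["signal"] + [f"noise{i}" for i in range(noise)]]
    return X, y


class TestFilters:
    def test_feature_identical_to_class_has_unit_pearson(self):
        y = np.array([0, 0, 1, 1])
        X = pd.DataFrame({"a": y.astype(float), "b": [0.2, 0.9, 0.1, 0.5]})
        assert filter_scores(X, y, "pearson")["a"] == pytest.approx(1.0)

    def test_constant_feature_scores_zero_under_both(self):
        y = np.array([0, 1, 0, 1])
        X = pd.DataFrame({"c": [0.5] * 4})
        assert filter_scores(X, y, "pearson")["c"] == 0.0
        assert filter_scores(X, y, "chi2")["c"] == pytest.approx(0.0)

    def test_chi2_hand_example(self):
        # observed class sums (0, 2) against expectation (1, 1): 1 + 1 = 2
        X = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0]})
        y = np.array([0, 0, 1, 1])
        assert filter_scores(X, y, "chi2")["a"] == pytest.approx(2.0)

    def test_negative_values_rejected_under_chi2(self):
        with pytest.raises(ValueError):
            filter_scores(pd.DataFrame({"a": [-1.0, 1.0]}), np.array([0, 1]), "chi2")

    def test_non_binary_y_rejected(self):
        with pytest.raises(ValueError):
            filter_scores(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), np.array([0, 1, 2]),
                          "pearson")


class TestRfe:
    def test_target_equal_to_total_is_identity(self):
        X, y = _planted()
        res = rfe_rank(X, y, target_size=X.shape[1])
        assert set(res.selected) == set(X.columns)

    def test_planted_feature_survives_to_size_one(self):
        X, y = _planted(n=400, noise=9, seed=1)
        res = rfe_rank(X, y, target_size=1, seed=1)
        assert res.selected == ["signal"]

    def test_duplicated_columns_tie_broken_deterministically(self):
        X, y = _planted(n=200, noise=4, seed=2)
        X = X.copy()
        X["signal2"] = X["signal"]
        res = rfe_rank(X, y, target_size=1, seed=2)
        assert len(res.selected) == 1
        assert res.selected[0] in ("signal", "signal2")

    def test_importance_orders_survivors_highest(self):
        X, y = _planted(n=300, noise=6, seed=3)
        res = rfe_rank(X, y, target_size=2, seed=3)
        imp = res.importance
        worst_selected = min(imp[f] for f in res.selected)
        best_unselected = max(imp[f] for f in X.columns if f not in res.selected)
        assert worst_selected > best_unselected


class TestEmbedded:
    def test_planted_feature_has_max_rf_importance(self):
        X, y = _planted(n=400, noise=9, seed=4)
        imp = embedded_importance(X, y, "rf", seed=0)
        assert max(imp, key=imp.get) == "signal"

    @pytest.mark.parametrize("model", ["rf", "gbm", "l2logreg"])
    def test_deterministic_under_fixed_seed(self, model):
        X, y = _planted(n=120, noise=5, seed=5)
        a = embedded_importance(X, y, model, seed=7)
        b = embedded_importance(X, y, model, seed=7)
        assert a == b

    def test_single_class_rejected(self):
        X, _ = _planted(n=50)
        with pytest.raises(ValueError):
            embedded_importance(X, np.zeros(50, dtype=int), "rf")

    def test_importances_non_negative(self):
        X, y = _planted(n=120, noise=5, seed=6)
        for model in ("rf", "gbm", "l2logreg"):
            assert all(v >= 0 for v in embedded_importance(X, y, model).values())


class TestSelectTop:
    def test_ordering(self):
        assert select_top({"a": 3.0, "b": 1.0, "c": 2.0}, 2) == ["a", "c"]

    def test_tie_broken_by_feature_id(self):
        assert select_top({"b": 1.0, "a": 1.0}, 1) == ["a"]

    def test_k_clipped_to_available(self):
        assert select_top({"a": 1.0, "b": 0.5}, 10) == ["a", "b"]


class TestCvScore:
    def test_perfectly_separating_feature_scores_one(self):
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"s": np.concatenate([np.zeros(30), np.ones(30)])})
        assert technique_cv_score(["s"], X, y) == 1.0

    def test_permuted_labels_score_near_half(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.random((200, 5)), columns=list("abcde"))
        accs = []
        for rep in range(20):
            y = rng.permutation(np.repeat([0, 1], 100))
            accs.append(technique_cv_score(list("abcde"), X, y, seed=rep))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * max(se, 0.01)

    def test_identical_subsets_score_identically(self):
        X, y = _planted(n=120, noise=4, seed=8)
        cols = list(X.columns[:3])
        assert technique_cv_score(cols, X, y, seed=1) == technique_cv_score(
            cols, X, y, seed=1
        )


class TestVoteRank:
    def test_hand_traced_example(self):
        results = [
            FsResult("pearson", ["f1", "f2"], {"f1": 1.0, "f2": 0.5}),
            FsResult("chi2", ["f1", "f3"], {"f1": 1.0, "f3": 0.5}),
            FsResult("rfe", ["f1", "f2"], {"f1": 1.0, "f2": 0.5}),
        ]
        tally = vote_rank(results, winner="pearson")
        assert tally.votes == {"f1": 3, "f2": 2, "f3": 1}
        assert tally.ranking == ["f1", "f2", "f3"]

    def test_unanimous_feature_ranked_first(self):
        results = [
            FsResult(t, ["star", f"x{i}"], {"star": 1.0, f"x{i}": 0.1})
            for i, t in enumerate(TECHNIQUES)
        ]
        tally = vote_rank(results, winner="pearson")
        assert tally.votes["star"] == 6
        assert tally.ranking[0] == "star"

    def test_vote_tie_broken_by_winner_importance(self):
        results = [
            FsResult("pearson", ["f2", "f3"], {"f2": 0.1, "f3": 0.9}),
            FsResult("chi2", ["f1"], {"f1": 1.0}),
        ]
        tally = vote_rank(results, winner="pearson")
        assert tally.ranking.index("f3") < tally.ranking.index("f2")

    def test_duplicate_technique_ids_rejected(self):
        r = FsResult("pearson", ["a"], {"a": 1.0})
        with pytest.raises(ValueError):
            vote_rank([r, r], winner="pearson")

    def test_vote_conservation_on_random_inputs(self, rng):
        features = [f"f{i}" for i in range(40)]
        for _ in range(20):
            results = []
            for t in TECHNIQUES:
                chosen = list(rng.choice(features, size=rng.integers(1, 20),
                                         replace=False))
                results.append(FsResult(t, chosen, {f: 1.0 for f in chosen}))
            tally = vote_rank(results, winner="rfe")
            assert sum(tally.votes.values()) == sum(len(r.selected) for r in results)

    def test_added_selection_never_lowers_relative_rank(self):
        base = [
            FsResult("pearson", ["a", "b"], {"a": 0.9, "b": 0.8}),
            FsResult("chi2", ["b"], {"b": 1.0}),
        ]
        before = vote_rank(base, winner="pearson").ranking
        extra = base + [FsResult("rfe", ["a"], {"a": 1.0})]
        after = vote_rank(extra, winner="pearson").ranking
        assert before.index("a") >= after.index("a")


class TestVotingFeatureSelector:
    def test_planted_features_dominate_ranking(self, balanced_xy):
        X, y, truth = balanced_xy
        sel = VotingFeatureSelector(k=40, random_state=3).fit(X, y)
        planted = set(truth.informative_ids) & set(X.columns)
        top = set(sel.ranking_[: len(planted) + 10])
        assert len(planted & top) >= 0.8 * len(planted)

    def test_fit_is_deterministic(self, balanced_xy):
        X, y, _ = balanced_xy
        a = VotingFeatureSelector(k=30, random_state=9).fit(X, y)
        b = VotingFeatureSelector(k=30, random_state=9).fit(X, y)
        assert a.ranking_ == b.ranking_ and a.winner_ == b.winner_

    def test_transform_returns_ranked_columns(self, balanced_xy):
        X, y, _ = balanced_xy
        sel = VotingFeatureSelector(k=20, random_state=1).fit(X, y)
        out = sel.transform(X)
        assert list(out.columns) == sel.ranking_
        assert len(sel.ranking_) <= 6 * 20
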