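"""Attributions, subgroup fairness, rank correlations, severity profile."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from speechscreen.reporting import (
    demographic_parity_gap,
    feature_attributions,
    probability_severity_profile,
    spearman_rank,
    subgroup_performance,
)


class TestTreeAttributions:
    def test_constant_model_attributes_nothing(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        y = np.full(30, 5.0)
        model = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
        rep = feature_attributions(model, X, mode="tree")
        assert rep.base_value == pytest.approx(5.0)
        assert np.abs(rep.contributions).max() == pytest.approx(0.0)

    def test_stump_matches_brute_force_shapley(self):
        """For a depth-1 tree on one informative feature, the Shapley value
        of the split feature is leaf-mean minus root-mean and every other
        feature gets zero."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = np.where(X[:, 0] > 0, 10.0, -10.0)
        model = RandomForestRegressor(
            n_estimators=1, max_depth=1, random_state=0, bootstrap=False
        ).fit(X, y)
        rep = feature_attributions(model, X, mode="tree")
        tree = model.estimators_[0].tree_
        root_mean = tree.value[0, 0, 0]
        for i in range(20):
            expected = model.predict(X[i : i + 1])[0] - root_mean
            assert rep.contributions[i, 0] == pytest.approx(expected, abs=1e-9)
            assert rep.contributions[i, 1:] == pytest.approx(0.0, abs=1e-12)
        mass = np.abs(rep.contributions).sum(axis=0)
        assert mass[0] == pytest.approx(mass.sum())

    def test_local_accuracy_for_classifier(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 6))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(scale=0.5, size=120) > 0
        model = RandomForestClassifier(
            n_estimators=25, max_depth=8, random_state=0
        ).fit(X, y)
        rep = feature_attributions(model, X[:50], mode="tree")
        recon = rep.base_value + rep.contributions.sum(axis=1)
        assert np.abs(recon - model.predict_proba(X[:50])[:, 1]).max() < 1e-6

    def test_feature_name_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = df["a"] > 0
        model = RandomForestClassifier(n_estimators=5, random_state=0).fit(df, y)
        wrong = df.rename(columns={"a": "z"})
        with pytest.raises(ValueError, match="training order"):
            feature_attributions(model, wrong, mode="tree")

    def test_permutation_mode_returns_global_ranking(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 4))
        y = X[:, 2] > 0
        model = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        rep = feature_attributions(model, X, mode="permutation", labels=y, seed=0)
        assert rep.contributions is None
        assert rep.ranking[0] == "f2"


class TestDemographicParity:
    @pytest.mark.parametrize(
        "pred, groups, expected",
        [
            ([1, 0, 1, 0], ["a", "a", "b", "b"], 0.0),
            ([1, 0, 0, 0, 0, 1, 1, 1, 0, 0], ["a"] * 5 + ["b"] * 5, 0.4),
        ],
    )
    def test_pairwise_rate_gaps(self, pred, groups, expected):
        assert demographic_parity_gap(
            np.array(pred, dtype=bool), groups
        ) == pytest.approx(expected)

    def test_three_groups_brute_force_max(self):
        pred = np.array([1] + [0] * 9 + [1] * 3 + [0] * 7 + [1] * 4 + [0] * 6, dtype=bool)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        assert demographic_parity_gap(pred, groups) == pytest.approx(0.3)

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(size=50) < 0.5
        groups = np.array(["x"] * 25 + ["y"] * 25)
        relabeled = np.where(groups == "x", "y", "x")
        assert demographic_parity_gap(pred, groups) == pytest.approx(
            demographic_parity_gap(pred, relabeled)
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            demographic_parity_gap(np.array([True, False]), ["a", "a"])


class TestSubgroupPerformance:
    def test_identical_groups_identical_metrics(self):
        labels = np.array([0, 0, 1, 1] * 10, dtype=bool)
        scores = np.tile([0.1, 0.6, 0.4, 0.9], 10)
        groups = np.array((["a"] * 4 + ["b"] * 4) * 5)
        rep = subgroup_performance(labels, scores, groups, min_group_size=5)
        assert rep.per_group["a"].metrics == rep.per_group["b"].metrics
        assert rep.parity_gap == pytest.approx(0.0)
        assert sum(rep.group_sizes.values()) == len(labels)

    def test_small_groups_flagged_not_dropped(self):
        labels = np.array([0, 1] * 6, dtype=bool)
        scores = np.linspace(0, 1, 12)
        groups = np.array(["big"] * 10 + ["tiny"] * 2)
        rep = subgroup_performance(labels, scores, groups, min_group_size=5)
        assert "tiny" in rep.flagged_small
        assert "tiny" in rep.per_group


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rank(x, x**3).r == pytest.approx(1.0)
        assert spearman_rank(x, -x).r == pytest.approx(-1.0)

    def test_ties_match_brute_force_midranks(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]

        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                mid = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = mid
                i = j + 1
            return np.array(ranks)

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rank(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            x = rng.choice(np.arange(10.0), size=n)
            y = rng.choice(np.arange(10.0), size=n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rank(x, y).r == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_flagged(self):
        res = spearman_rank([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined


class TestSeverityProfile:
    def test_constant_scores_equal_means(self):
        scores = np.full(8, 0.4)
        mmse = [28, 27, 24, 22, 15, 12, 8, 5]
        profile, corr = probability_severity_profile(scores, mmse)
        assert (profile["mean_score"] == 0.4).all()
        assert not corr.defined

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            probability_severity_profile(np.array([]), [])
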