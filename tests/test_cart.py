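"""Gini tree growth, pruning, prediction, and confusion-matrix metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lesionload import (
    TreeConfig,
    TreeNode,
    classification_report,
    gini,
    grow_tree,
    make_planted_rule_cohort,
    predict,
    prune,
)


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0, 0), 0.0), ((5, 5), 0.5), ((18, 12, 4), 0.5813)],
    )
    def test_formula(self, counts, expected):
        assert gini(counts) == pytest.approx(expected, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))

    def test_dict_input(self):
        assert gini({"a": 5, "b": 5}) == pytest.approx(0.5)


def brute_force_best_split(X, y, min_size=1):
    """Enumerate every (feature, midpoint threshold) split; best Gini decrease."""
    parent = gini(np.unique(y, return_counts=True)[1])
    best = None
    for col in X.columns:
        u = np.unique(X[col])
        for thr in (u[:-1] + u[1:]) / 2:
            left = X[col].to_numpy() < thr
            if left.sum() < min_size or (~left).sum() < min_size:
                continue
            g = (
                left.sum() * gini(np.unique(y[left], return_counts=True)[1])
                + (~left).sum() * gini(np.unique(y[~left], return_counts=True)[1])
            ) / len(y)
            dec = parent - g
            if best is None or dec > best[0] + 1e-12:
                best = (dec, col, thr)
    return best


class TestGrowTree:
    def test_recovers_separating_threshold_at_midpoint(self):
        # perfectly separated at 15 with a gap from 13 to 17
        X = pd.DataFrame({"A": [5, 9, 13, 17, 21, 25], "B": [1, 1, 1, 1, 1, 2]})
        y = np.array(["lo", "lo", "lo", "hi", "hi", "hi"], dtype=object)
        tree = grow_tree(X, y, TreeConfig(max_depth=2, min_terminal_size=1))
        assert tree.feature == "A"
        assert tree.threshold == pytest.approx(15.0)
        assert tree.left.class_counts == {"lo": 3, "hi": 0}
        assert tree.right.class_counts == {"lo": 0, "hi": 3}

    def test_single_class_gives_single_leaf(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        tree = grow_tree(X, ["a", "a", "a"])
        assert tree.is_leaf and tree.prediction == "a"

    def test_constant_feature_never_selected(self):
        X = pd.DataFrame({"const": [7.0] * 6, "good": [1, 2, 3, 10, 11, 12]})
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        tree = grow_tree(X, y, TreeConfig(min_terminal_size=1))
        assert tree.feature == "good"

    @pytest.mark.parametrize("seed", range(10))
    def test_root_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["f1", "f2", "f3"])
        y = np.asarray(rng.choice(["a", "b", "c"], size=20), dtype=object)
        tree = grow_tree(X, y, TreeConfig(max_depth=1, min_terminal_size=1))
        best = brute_force_best_split(X, y)
        if best is None:
            assert tree.is_leaf
        else:
            assert tree.feature == best[1]
            assert tree.threshold == pytest.approx(best[2])

    def test_deterministic(self):
        X, y = make_planted_rule_cohort(50, seed=3)
        t1 = grow_tree(X, y).to_dict()
        t2 = grow_tree(X, y).to_dict()
        assert t1 == t2

    def test_respects_depth_and_terminal_size(self):
        X, y = make_planted_rule_cohort(100, seed=5, label_noise=0.2)
        tree = grow_tree(X, y, TreeConfig(max_depth=2, min_terminal_size=3))
        assert tree.tree_depth <= 2
        for leaf in tree.leaves():
            assert leaf.n >= 3

    def test_every_split_decreases_weighted_gini(self):
        X, y = make_planted_rule_cohort(120, seed=8, label_noise=0.1)
        tree = grow_tree(X, y)
        for node in tree.internal_nodes():
            parent = gini(node.class_counts)
            child_g = (
                node.left.n * gini(node.left.class_counts)
                + node.right.n * gini(node.right.class_counts)
            ) / node.n
            assert child_g < parent

    def test_training_accuracy_beats_majority_baseline(self):
        X, y = make_planted_rule_cohort(90, seed=2, label_noise=0.1)
        tree = grow_tree(X, y)
        acc = (predict(tree, X) == y).mean()
        baseline = max(np.unique(y, return_counts=True)[1]) / len(y)
        assert acc >= baseline

    def test_child_counts_sum_to_parent(self):
        X, y = make_planted_rule_cohort(80, seed=4)
        tree = grow_tree(X, y)
        for node in tree.internal_nodes():
            for c in node.class_counts:
                assert (
                    node.left.class_counts[c] + node.right.class_counts[c]
                    == node.class_counts[c]
                )

    def test_matches_sklearn_on_separable_data(self):
        """Independent oracle: sklearn's CART finds the same root split."""
        sklearn = pytest.importorskip("sklearn.tree")
        X, y = make_planted_rule_cohort(150, seed=12)
        clf = sklearn.DecisionTreeClassifier(
            criterion="gini", max_depth=2, min_samples_leaf=3, random_state=0
        ).fit(X, y)
        tree = grow_tree(X, y, TreeConfig())
        assert X.columns[clf.tree_.feature[0]] == tree.feature
        # both thresholds must lie in the planted root gap
        assert 13.0 <= clf.tree_.threshold[0] <= 17.0
        assert 13.0 <= tree.threshold <= 17.0
        assert (clf.predict(X) == predict(tree, X)).all()


class TestPredict:
    def test_single_leaf_constant(self):
        tree = TreeNode(0, 0, {"a": 3}, "a")
        assert list(predict(tree, pd.DataFrame({"x": [1, 2]}))) == ["a", "a"]

    def test_boundary_row_goes_right(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 9.0, 10.0]})
        y = np.array(["lo", "lo", "hi", "hi"], dtype=object)
        tree = grow_tree(X, y, TreeConfig(min_terminal_size=1))
        thr = tree.threshold
        assert predict(tree, pd.DataFrame({"A": [thr]}))[0] == "hi"
        assert predict(tree, pd.DataFrame({"A": [thr - 1e-9]}))[0] == "lo"

    def test_training_rows_recovered_on_pure_tree(self):
        X, y = make_planted_rule_cohort(60, seed=1)
        tree = grow_tree(X, y, TreeConfig(min_terminal_size=1))
        assert (predict(tree, X) == y).all()

    def test_missing_feature_is_error(self):
        X, y = make_planted_rule_cohort(30, seed=6)
        tree = grow_tree(X, y)
        with pytest.raises(KeyError):
            predict(tree, pd.DataFrame({"unrelated": [1.0]}))
        with pytest.raises(ValueError, match="missing"):
            bad = X.iloc[:1].copy()
            bad.iloc[0, bad.columns.get_loc(tree.feature)] = np.nan
            predict(tree, bad)


class TestPrune:
    def test_pure_tree_unchanged(self):
        X, y = make_planted_rule_cohort(60, seed=1)
        cfg = TreeConfig(seed=1)
        tree = grow_tree(X, y, cfg)
        pruned = prune(tree, X, y, cfg)
        assert pruned.to_dict() == tree.to_dict()

    def test_single_leaf_fixpoint(self):
        X = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        y = ["a", "a", "a"]
        cfg = TreeConfig()
        tree = grow_tree(X, y, cfg)
        assert prune(tree, X, y, cfg).is_leaf

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_split_pruned_on_planted_depth1_rule(self, seed):
        """A depth-2 tree grown on a depth-1 generator with label noise
        should lose its noise-fitting second split under CV pruning."""
        X, y = make_planted_rule_cohort(60, seed=seed, depth=1, label_noise=0.15)
        cfg = TreeConfig(seed=seed)
        grown = grow_tree(X, y, cfg)
        pruned = prune(grown, X, y, cfg)
        assert pruned.tree_depth <= grown.tree_depth
        assert pruned.tree_depth <= 1

    def test_never_increases_depth(self):
        X, y = make_planted_rule_cohort(100, seed=9, label_noise=0.25)
        cfg = TreeConfig(seed=9)
        grown = grow_tree(X, y, cfg)
        assert prune(grown, X, y, cfg).tree_depth <= grown.tree_depth

    @pytest.mark.parametrize("seed", [1, 7])
    def test_planted_depth2_rule_recovery(self, seed):
        """Root feature and in-gap thresholds recovered on planted cohorts.

        Spot checks on two cohorts; the 50-seed frequency bound lives in
        the acceptance suite.
        """
        X, y = make_planted_rule_cohort(200, seed=seed, margin=4.0)
        cfg = TreeConfig(seed=seed)
        tree = prune(grow_tree(X, y, cfg), X, y, cfg)
        assert not tree.is_leaf
        assert tree.feature == "PMd_percent"
        assert 13.0 <= tree.threshold <= 17.0
        second = [n for n in (tree.left, tree.right) if n is not None and not n.is_leaf]
        for node in second:
            if node.feature == "PMv_percent":
                assert 13.0 <= node.threshold <= 17.0


class TestClassificationReport:
    def test_printed_count_accuracies(self):
        y_true = ["A"] * 27 + ["B"] * 7
        y_pred = ["A"] * 27 + ["A"] * 7
        assert classification_report(y_true, y_pred).accuracy_percent == pytest.approx(
            100 * 27 / 34
        )
        y_pred2 = ["A"] * 27 + ["B"] * 3 + ["A"] * 4
        assert classification_report(y_true, y_pred2).accuracy_percent == pytest.approx(
            100 * 30 / 34
        )

    def test_ppv_from_confusion_counts(self):
        # 5 predictions of class P, 4 of them true -> PPV 80%
        y_pred = ["P"] * 5 + ["G"] * 29
        y_true = ["P"] * 4 + ["G"] * 30
        rep = classification_report(y_true, y_pred)
        assert rep.per_class.loc["P", "ppv"] == pytest.approx(80.0)

    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        rep = classification_report(y, y)
        assert rep.accuracy_percent == 100.0
        assert (rep.per_class.to_numpy() == 100.0).all()

    def test_undefined_metrics_are_nan(self):
        rep = classification_report(["a", "a"], ["a", "a"], class_order=["a", "b"])
        assert np.isnan(rep.per_class.loc["b", "ppv"])  # b never predicted
        assert np.isnan(rep.per_class.loc["b", "sensitivity"])  # b never true

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_report([], [])
        with pytest.raises(ValueError):
            classification_report(["a"], ["a", "b"])

    def test_confusion_matrix_row_sums_are_class_counts(self):
        rng = np.random.default_rng(13)
        y_true = rng.choice(["x", "y", "z"], size=40)
        y_pred = rng.choice(["x", "y", "z"], size=40)
        rep = classification_report(y_true, y_pred)
        for c in rep.confusion.index:
            assert rep.confusion.loc[c].sum() == (y_true == c).sum()


class TestSerialization:
    def test_json_roundtrip(self):
        X, y = make_planted_rule_cohort(80, seed=15)
        tree = grow_tree(X, y)
        again = TreeNode.from_dict(tree.to_dict())
        assert again.to_dict() == tree.to_dict()
        assert (predict(again, X) == predict(tree, X)).all()

    def test_render_mentions_split_rule(self):
        X, y = make_planted_rule_cohort(80, seed=15)
        text = grow_tree(X, y).render()
        assert "PMd_percent <" in text
        assert "predict" in text
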