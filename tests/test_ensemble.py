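"""CART, cross-validation, ROC/PR, selection — checked against brute force.

The oracles here are written independently of the implementation: a plain
recursive greedy CART in pure Python (same tie rules, exhaustive scan of
features at each node), AUC by explicit positive-negative pair counting,
and metric identities evaluated from first principles.
"""

import numpy as np
import pandas as pd
import pytest

from strscreen.ensemble import (CVScheme, Hyperparameters, default_grid,
                                evaluate, exhaustive_feature_selection,
                                feature_importances, fit_tree, gini_impurity,
                                grid_search, load_model, pr_curve,
                                repeated_stratified_kfold, roc_auc,
                                roc_curve, save_model, stratified_split)
from strscreen.harmonize import LabeledMatrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_gini(counts):
    total = sum(counts)
    return 1.0 - sum((c / total) ** 2 for c in counts)


def oracle_tree(X, y, max_depth):
    """Pure-python greedy CART; returns nested (value, feature, kids) tuples.

    Same conventions as the implementation under test: split on the
    feature with the largest weighted impurity decrease (strictly positive),
    lowest index on ties, flag 0 to the left.
    """
    rows = list(range(len(y)))

    def grow(rows, depth):
        value = (sum(y[i] for i in rows), sum(1 - y[i] for i in rows))
        node = {"value": value, "samples": len(rows),
                "gini": oracle_gini(value), "feature": None}
        if 0 in value or depth >= max_depth:
            return node
        best = None
        for f in range(X.shape[1]):
            left = [i for i in rows if X[i][f] == 0]
            right = [i for i in rows if X[i][f] == 1]
            if not left or not right:
                continue
            dec = node["gini"]
            for part in (left, right):
                cnt = (sum(y[i] for i in part), sum(1 - y[i] for i in part))
                dec -= len(part) / len(rows) * oracle_gini(cnt)
            if best is None or dec > best[0] + 1e-12:
                best = (dec, f, left, right)
        if best is None or best[0] <= 1e-12:
            return node
        node["feature"] = best[1]
        node["left"] = grow(best[2], depth + 1)
        node["right"] = grow(best[3], depth + 1)
        return node

    return grow(rows, 0)


def oracle_predict(node, row):
    while node["feature"] is not None:
        node = node["right"] if row[node["feature"]] == 1 else node["left"]
    value = node["value"]
    return 1 if value[0] >= value[1] else 0, value[0] / sum(value)


def oracle_auc(y, s):
    pairs = [(si, sj) for si, yi in zip(s, y) if yi == 1
             for sj, yj in zip(s, y) if yj == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs)
    return wins / len(pairs)


def assert_same_tree(node, oracle_node, feature_names):
    assert node.samples == oracle_node["samples"]
    assert node.value == oracle_node["value"]
    assert node.gini == pytest.approx(oracle_node["gini"], abs=1e-12)
    assert node.feature == oracle_node["feature"]
    if node.feature is not None:
        assert_same_tree(node.left, oracle_node["left"], feature_names)
        assert_same_tree(node.right, oracle_node["right"], feature_names)


def random_dataset(rng, n=60, k=5):
    X = rng.integers(0, 2, size=(n, k))
    # labels correlate with a random subset of features plus noise
    w = rng.integers(0, 2, size=k)
    score = X @ w + rng.normal(0, 1.0, size=n)
    y = (score > np.median(score)).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# Gini and tree fitting
# ---------------------------------------------------------------------------

class TestGini:
    def test_balanced_node_is_maximally_impure(self):
        assert gini_impurity((50, 50)) == 0.5

    def test_training_root_counts(self):
        # 62 expanded vs 878 non-expanded rows: 1 - (62/940)^2 - (878/940)^2
        assert gini_impurity((62, 878)) == pytest.approx(0.1232, abs=1e-4)

    def test_pure_node(self):
        assert gini_impurity((0, 10)) == 0.0

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestFitTree:
    def test_perfect_feature_gives_depth_one_pure_tree(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 0, 1])
        tree = fit_tree((X, y))
        assert tree.root.feature == 1
        assert tree.root.left.gini == 0.0 and tree.root.right.gini == 0.0
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    def test_constant_labels_give_single_leaf(self):
        X = np.array([[0], [1], [0]])
        y = np.array([1, 1, 1])
        tree = fit_tree((X, y))
        assert tree.root.is_leaf
        assert tree.predict(X).tolist() == [1, 1, 1]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_tree((np.zeros((0, 2)), np.zeros(0)))

    def test_child_sample_counts_sum_to_parent(self):
        rng = np.random.default_rng(5)
        X, y = random_dataset(rng)
        tree = fit_tree((X, y))
        for node in tree.nodes():
            if not node.is_leaf:
                assert node.left.samples + node.right.samples == node.samples
                assert (node.left.value[0] + node.right.value[0]
                        == node.value[0])

    def test_matches_brute_force_cart_on_many_random_datasets(self):
        """Structure, node statistics, predictions and scores all agree."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            X, y = random_dataset(rng)
            tree = fit_tree((X, y), Hyperparameters(max_depth=4))
            oracle = oracle_tree(X, y, max_depth=4)
            assert_same_tree(tree.root, oracle, tree.feature_names)
            pred = tree.predict(X)
            score = tree.predict_score(X)
            for i, row in enumerate(X):
                o_pred, o_score = oracle_predict(oracle, row)
                assert pred[i] == o_pred
                assert score[i] == pytest.approx(o_score, abs=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        X, y = random_dataset(rng)
        t1, t2 = fit_tree((X, y)), fit_tree((X, y))
        assert t1.root.to_dict() == t2.root.to_dict()


class TestPredict:
    def test_pure_leaf_scores_are_binary(self):
        X = np.array([[0], [1]])
        y = np.array([0, 1])
        tree = fit_tree((X, y))
        assert set(tree.predict_score(X)) == {0.0, 1.0}

    def test_single_leaf_constant_prediction(self):
        X = np.zeros((4, 2), dtype=int)
        y = np.array([1, 1, 1, 0])
        tree = fit_tree((X, y))
        assert tree.root.is_leaf
        assert tree.predict(np.array([[0, 1], [1, 0]])).tolist() == [1, 1]

    def test_leaf_tie_predicts_full_mutation(self):
        X = np.array([[0], [0], [1], [1]])
        y = np.array([1, 0, 1, 0])
        tree = fit_tree((X, y))
        assert tree.predict(X).tolist() == [1, 1, 1, 1]

    def test_non_binary_value_rejected(self):
        X = np.array([[0, 1], [1, 0]])
        tree = fit_tree((X, np.array([0, 1])))
        with pytest.raises(ValueError, match="feature"):
            tree.predict(np.array([[2, 0]]))


# ---------------------------------------------------------------------------
# Splitting and cross-validation
# ---------------------------------------------------------------------------

def toy_matrix(n, n_pos, tools=("a", "b")):
    idx = pd.MultiIndex.from_tuples([(f"S{i}", "HTT") for i in range(n)],
                                    names=["sample", "locus"])
    data = pd.DataFrame(0, index=idx, columns=list(tools))
    labels = pd.Series(["full_mutation"] * n_pos
                       + ["non_full_mutation"] * (n - n_pos), index=idx)
    return LabeledMatrix(data, labels, tuple(tools))


class TestStratifiedSplit:
    def test_published_split_arithmetic(self):
        matrix = toy_matrix(1176, 78)
        train, test = stratified_split(matrix, 0.2, seed=0)
        assert (len(train), len(test)) == (940, 236)

    def test_small_balanced_split_keeps_both_classes(self):
        matrix = toy_matrix(10, 5)
        train, test = stratified_split(matrix, 0.2, seed=1)
        assert len(test) == 2
        assert set(test.labels) == {"full_mutation", "non_full_mutation"}

    def test_same_seed_reproduces_partition(self):
        matrix = toy_matrix(50, 10)
        a = stratified_split(matrix, 0.2, seed=9)
        b = stratified_split(matrix, 0.2, seed=9)
        assert a[1].data.index.equals(b[1].data.index)

    def test_proportions_preserved_to_rounding(self):
        matrix = toy_matrix(200, 40)
        train, test = stratified_split(matrix, 0.25, seed=3)
        assert (test.labels == "full_mutation").sum() == 10
        assert (train.labels == "full_mutation").sum() == 30


class TestRepeatedStratifiedKFold:
    def test_fifty_splits_from_five_repeats_of_ten_folds(self):
        matrix = toy_matrix(100, 20)
        splits = repeated_stratified_kfold(matrix, CVScheme(10, 5, seed=0))
        assert len(splits) == 50

    def test_validation_folds_partition_each_repeat(self):
        matrix = toy_matrix(53, 11)
        splits = repeated_stratified_kfold(matrix, CVScheme(5, 3, seed=2))
        for rep in range(3):
            fold_union = np.concatenate(
                [val for _, val in splits[rep * 5:(rep + 1) * 5]])
            assert sorted(fold_union) == list(range(53))

    def test_two_fold_balanced_classes_per_fold(self):
        matrix = toy_matrix(4, 2)
        splits = repeated_stratified_kfold(matrix, CVScheme(2, 1, seed=0))
        y = matrix.y
        for _, val in splits:
            assert y[val].sum() == 1

    def test_train_and_validation_disjoint(self):
        matrix = toy_matrix(30, 6)
        for train, val in repeated_stratified_kfold(matrix,
                                                    CVScheme(3, 2, seed=4)):
            assert not set(train) & set(val)


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_matches_pair_counting_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            auc = roc_auc(y, s)
            assert auc == pytest.approx(oracle_auc(y, s), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_roc_curve_endpoints(self):
        pts = roc_curve([0, 1], [0.2, 0.9])
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_pr_curve_final_recall_is_one(self):
        pts = pr_curve([0, 1, 1], [0.2, 0.9, 0.8])
        assert pts[-1][0] == 1.0


# ---------------------------------------------------------------------------
# Feature selection and grid search
# ---------------------------------------------------------------------------

def informative_matrix(seed=0, n=120, informative=("a",),
                       noise=("b", "c", "d", "e")):
    rng = np.random.default_rng(seed)
    tools = tuple(informative) + tuple(noise)
    y = np.array([1] * (n // 4) + [0] * (n - n // 4))
    cols = {}
    for t in informative:
        flip = rng.random(n) < 0.05
        cols[t] = np.where(flip, 1 - y, y)
    for t in noise:
        cols[t] = rng.integers(0, 2, size=n)
    idx = pd.MultiIndex.from_tuples([(f"S{i}", "HTT") for i in range(n)],
                                    names=["sample", "locus"])
    data = pd.DataFrame(cols, index=idx)[list(tools)]
    labels = pd.Series(np.where(y == 1, "full_mutation",
                                "non_full_mutation"), index=idx)
    return LabeledMatrix(data, labels, tools)


class TestExhaustiveFeatureSelection:
    def test_informative_feature_recovered(self, fast_scheme):
        matrix = informative_matrix(seed=3)
        best, table = exhaustive_feature_selection(matrix,
                                                   scheme=fast_scheme)
        assert "a" in best

    def test_all_subsets_enumerated(self, fast_scheme):
        matrix = informative_matrix(seed=1, noise=("b", "c"))
        _, table = exhaustive_feature_selection(
            matrix, tools=("a", "b", "c"), scheme=fast_scheme)
        assert len(table) == 7

    def test_duplicate_columns_tie_broken_toward_smaller_subset(self,
                                                                fast_scheme):
        matrix = informative_matrix(seed=2, informative=("a", "b"), noise=())
        # b duplicates a's construction; singletons tie with the pair
        matrix.data["b"] = matrix.data["a"]
        best, _ = exhaustive_feature_selection(matrix, scheme=fast_scheme)
        assert best == ("a",)

    def test_best_subset_beats_every_singleton(self, ega_matrix):
        scheme = CVScheme(k=5, repeats=1, seed=3)
        best, table = exhaustive_feature_selection(ega_matrix, scheme=scheme)
        scored = {tuple(s): auc for s, auc in
                  zip(table["subset"], table["mean_auc"])}
        best_auc = scored[tuple(best)]
        for tool in ega_matrix.tools:
            assert best_auc >= scored[(tool,)] - 1e-12


class TestGridSearch:
    def test_grid_of_one_returns_it(self, fast_scheme):
        matrix = informative_matrix(seed=4)
        hp = Hyperparameters(max_depth=2)
        assert grid_search(matrix, ("a",), [hp], fast_scheme) == hp

    def test_separable_data_prefers_simplest_model(self, fast_scheme):
        matrix = informative_matrix(seed=5, informative=("a",), noise=("b",))
        matrix.data["a"] = matrix.y  # perfectly separating flag
        best = grid_search(matrix, ("a", "b"), None, fast_scheme)
        assert best.max_depth == 1
        assert best.min_samples_leaf == max(
            hp.min_samples_leaf for hp in default_grid())

    def test_selected_depth_bounded_by_informative_features(self, ega_matrix):
        scheme = CVScheme(k=5, repeats=1, seed=6)
        best = grid_search(ega_matrix, ("eh_v3", "stretch", "exstra"),
                           None, scheme)
        assert best.max_depth <= 3


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

class TestEvaluate:
    @pytest.mark.parametrize("tp, fp, fn, f1_pct", [
        (41, 9, 0, 90),    # precision .82, recall 1.00
        (9, 1, 0, 95),     # precision .90, recall 1.00
        (83, 0, 17, 91),   # precision 1.00, recall .83
        (89, 0, 11, 94),   # precision 1.00, recall .89
    ])
    def test_f1_identities_match_printed_percentages(self, tp, fp, fn,
                                                     f1_pct):
        y = [1] * (tp + fn) + [0] * (fp + 200)
        pred = [1] * tp + [0] * fn + [1] * fp + [0] * 200
        report = evaluate(y, pred)
        assert round(100 * report.per_class["full_mutation"]["f1"]) == f1_pct

    def test_all_correct_gives_unit_metrics(self):
        report = evaluate([1, 0, 1], [1, 0, 1])
        fm = report.per_class["full_mutation"]
        assert (fm["precision"], fm["recall"], fm["f1"],
                report.accuracy) == (1, 1, 1, 1)

    def test_recall_from_confusion_counts(self):
        y = [1] * 62 + [0] * 878
        pred = [1] * 45 + [0] * 17 + [1] * 5 + [0] * 873
        report = evaluate(y, pred)
        assert (report.tp, report.fn, report.fp, report.tn) == (45, 17, 5, 873)
        assert report.per_class["full_mutation"]["recall"] == pytest.approx(
            45 / 62)

    def test_macro_and_weighted_averages(self):
        y = [1, 1, 0, 0, 0, 0]
        pred = [1, 0, 0, 0, 0, 1]
        report = evaluate(y, pred)
        pc = report.per_class
        for metric in ("precision", "recall", "f1"):
            macro = np.mean([pc[c][metric] for c in pc])
            weighted = sum(pc[c][metric] * pc[c]["support"]
                           for c in pc) / 6
            assert report.macro[metric] == pytest.approx(macro)
            assert report.weighted[metric] == pytest.approx(weighted)

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        y, pred = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        report = evaluate(y, pred)
        assert report.n == 40


class TestFeatureImportances:
    def test_single_split_concentrates_importance(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 0, 1])
        imp = feature_importances(fit_tree((X, y), feature_names=("a", "b")))
        assert imp == {"a": 0.0, "b": 1.0}

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(3)
        X, y = random_dataset(rng)
        tree = fit_tree((X, y))
        if not tree.root.is_leaf:
            assert sum(feature_importances(tree).values()) == pytest.approx(1)

    def test_leaf_fraction_scores_match_direct_counting(self, ega_matrix):
        tree = fit_tree(ega_matrix, Hyperparameters(max_depth=3))
        scores = tree.predict_score(ega_matrix.X)
        for row, score in zip(ega_matrix.X, scores):
            leaf = tree._leaf_for(row)
            assert score == leaf.value[0] / leaf.samples


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, ega_matrix):
        tree = fit_tree(ega_matrix, Hyperparameters(max_depth=4))
        tree.metadata = {"seed": 1}
        path = tmp_path / "model.json"
        save_model(tree, path)
        loaded = load_model(path)
        assert loaded.feature_names == tree.feature_names
        assert loaded.metadata == {"seed": 1}
        assert np.array_equal(loaded.predict(ega_matrix.X),
                              tree.predict(ega_matrix.X))
        assert loaded.root.to_dict() == tree.root.to_dict()
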