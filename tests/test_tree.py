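import numpy as np
import pytest

from ecgfusion.spectral import beat_features
from ecgfusion.tree import (CartTree, IncrementalPlan, PrunedTree, best_split,
                            gini_index, grow_tree, incremental_train,
                            prune_path, tree_predict)

from _oracles import brute_best_split, brute_min_cost, enumerate_pruned_subtrees


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini_index([10, 0, 0, 0]) == 0.0

    def test_uniform_four_class_maximum(self):
        assert gini_index([5, 5, 5, 5]) == pytest.approx(0.75)

    def test_direct_evaluation(self):
        assert gini_index([3, 1]) == pytest.approx(0.375)

    def test_bounds_and_errors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 20, size=4)
            if counts.sum() == 0:
                continue
            g = gini_index(counts)
            assert 0.0 <= g <= 0.75 + 1e-12
        with pytest.raises(ValueError):
            gini_index([0, 0])
        with pytest.raises(ValueError):
            gini_index([-1, 2])


class TestBestSplit:
    def test_two_point_split(self):
        X = np.array([[1.0], [2.0]])
        y = np.array([0, 1])
        attr, thr, dec = best_split(X, y, 2)
        assert attr == 0
        assert thr == pytest.approx(1.5)
        assert dec == pytest.approx(0.5)  # parent gini of a 50/50 node

    def test_pure_node_is_leaf_signal(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        assert best_split(X, np.zeros(6, dtype=int), 2) is None

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 13))
        d = int(rng.integers(1, 4))
        X = np.round(rng.standard_normal((n, d)), 2)
        y = rng.integers(0, 3, size=n)
        got = best_split(X, y, 3)
        want = brute_best_split(X, [str(v) for v in y])
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got[2] == pytest.approx(want[2], abs=1e-10)
            assert (got[0], got[1]) == (want[0], pytest.approx(want[1]))


class TestGrowTree:
    def test_separable_data_reaches_perfect_training_accuracy(
            self, small_feature_problem):
        X, y = small_feature_problem
        tree = grow_tree(X, y)
        pred = PrunedTree(tree, 0.0, frozenset()).predict_label(X)
        assert np.all(pred == y)

    def test_min_samples_yields_single_leaf(self, small_feature_problem):
        X, y = small_feature_problem
        tree = grow_tree(X, y, min_samples=len(y))
        assert tree.root.is_leaf
        dist = tree_predict(tree, X[0])
        np.testing.assert_allclose(dist, [1 / 3] * 3)

    def test_max_depth_respected(self, small_feature_problem):
        X, y = small_feature_problem

        def depth(node):
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        for md in (1, 2, 3):
            assert depth(grow_tree(X, y, max_depth=md).root) <= md

    def test_sklearn_cross_check_root_split(self):
        """Independent CART (scikit-learn) picks the same root split."""
        sktree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 4))
        y = (X[:, 2] > 0.3).astype(int)  # unique dominant split
        attr, thr, _dec = best_split(X, y, 2)
        clf = sktree.DecisionTreeClassifier(criterion="gini",
                                            random_state=0).fit(X, y)
        assert clf.tree_.feature[0] == attr == 2
        # scikit-learn computes the midpoint after casting X to float32
        assert clf.tree_.threshold[0] == pytest.approx(thr, abs=1e-6)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(np.empty((0, 2)), np.empty(0))


class TestPrunePath:
    @pytest.fixture()
    def noisy_tree(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((40, 2))
        y = (X[:, 0] + 0.8 * rng.standard_normal(40) > 0).astype(int)
        return grow_tree(np.round(X, 1), [str(v) for v in y])

    def test_chain_ends(self, noisy_tree):
        chain = prune_path(noisy_tree)
        assert chain[0].alpha == 0.0
        assert chain[0].n_leaves == noisy_tree.n_leaves  # full tree at alpha=0
        assert chain[-1].n_leaves == 1                   # root-only at the end

    def test_chain_nested_and_strictly_shrinking(self, noisy_tree):
        chain = prune_path(noisy_tree)
        for a, b in zip(chain[:-1], chain[1:]):
            assert a.alpha < b.alpha
            assert a.collapsed <= b.collapsed
            assert b.n_leaves < a.n_leaves

    @pytest.mark.parametrize("trial", range(20))
    def test_chain_optimal_against_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(6, 16))
        X = np.round(rng.standard_normal((n, 2)), 1)
        y = rng.integers(0, 2, size=n)
        tree = grow_tree(X, [str(v) for v in y], max_depth=3)
        if len(tree.nodes()) > 11:
            tree = grow_tree(X, [str(v) for v in y], max_depth=2)
        chain = prune_path(tree)
        alphas = [m.alpha for m in chain] + [chain[-1].alpha + 2.0]
        for i, member in enumerate(chain):
            # the chain member minimizes C(T) + alpha|T| throughout its interval
            for alpha in (alphas[i], 0.5 * (alphas[i] + alphas[i + 1])):
                cost = member.training_misclassification + alpha * member.n_leaves
                assert cost == pytest.approx(brute_min_cost(tree, alpha),
                                             abs=1e-9)

    def test_subtree_enumeration_counts(self):
        # sanity of the oracle itself on a known shape: full binary depth 2
        X = np.array([[0.], [1.], [2.], [3.]])
        y = ["a", "b", "a", "b"]
        tree = grow_tree(X, y)
        subs = enumerate_pruned_subtrees(tree)
        assert frozenset() in subs
        assert frozenset({tree.root.id}) in subs


class TestPredict:
    def test_distribution_sums_to_one(self, small_feature_problem):
        X, y = small_feature_problem
        tree = grow_tree(X, y, max_depth=2)
        dist = tree_predict(tree, X)
        np.testing.assert_allclose(dist.sum(axis=1), 1.0)

    def test_feature_length_mismatch(self, small_feature_problem):
        X, y = small_feature_problem
        tree = grow_tree(X, y)
        with pytest.raises(ValueError):
            tree_predict(tree, np.zeros(7))

    def test_json_round_trip(self, small_feature_problem, tmp_path):
        X, y = small_feature_problem
        tree = grow_tree(X, y, max_depth=3)
        prune_path(tree)
        tree.to_json(tmp_path / "t.json")
        back = CartTree.from_json(tmp_path / "t.json")
        np.testing.assert_array_equal(
            PrunedTree(back, 0.0, frozenset()).predict_label(X),
            PrunedTree(tree, 0.0, frozenset()).predict_label(X))
        assert [m.alpha for m in back.alpha_sequence] == \
               [m.alpha for m in tree.alpha_sequence]


@pytest.fixture(scope="module")
def features_1000():
    rng = np.random.default_rng(17)
    centers = {"N": (0, 0), "S": (3, 0), "V": (0, 3), "F": (3, 3)}
    labels = rng.choice(list(centers), size=1000, p=[0.6, 0.1, 0.2, 0.1])
    X = np.stack([centers[l] for l in labels]).astype(float)
    X += 0.4 * rng.standard_normal(X.shape)
    return X, np.asarray(labels, dtype=object)


class TestIncremental:
    def test_fold_sizes_for_n_1000(self, features_1000):
        X, y = features_1000
        res = incremental_train(X, y, IncrementalPlan(seed=0))
        assert len(res.test_indices) == 100
        assert list(res.report["validation_size"]) == [800] * 9
        assert list(res.report["pool_size"])[0] == 100
        assert len(res.report) == 9

    def test_junk_rule_off_is_plain_repeated_training(self, features_1000):
        X, y = features_1000
        res = incremental_train(X, y, IncrementalPlan(seed=0, junk_rule="off"))
        assert list(res.report["junk_removed"]) == [0] * 9

    def test_junk_never_touches_validation_or_test(self, features_1000):
        X, y = features_1000
        plan = IncrementalPlan(seed=0)
        res = incremental_train(X, y, plan)
        pooled = set()
        for i in range(9):
            pooled |= set(res.folds[i])
        assert pooled.isdisjoint(res.test_indices)

    def test_separable_data_trains_perfectly(self, clean_dataset):
        X, y = clean_dataset
        feats = beat_features(X, segmented=True).features
        res = incremental_train(feats, y, IncrementalPlan(seed=1))
        acc = float(res.report["validation_accuracy"].max())
        assert acc >= 0.99

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            incremental_train(np.zeros((5, 2)), np.zeros(5), IncrementalPlan())

    def test_report_reproducible(self, features_1000):
        X, y = features_1000
        a = incremental_train(X, y, IncrementalPlan(seed=3))
        b = incremental_train(X, y, IncrementalPlan(seed=3))
        assert a.report.equals(b.report)
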