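import numpy as np
import pytest

from nichescheme.cart import (
    CartError,
    GrowthParams,
    assign_groups,
    best_split,
    brute_force_tree,
    cv_prune_1se,
    grow_tree,
)

TOY_X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
TOY_Y = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
LOOSE = GrowthParams(minsplit=2, minbucket=1, cp_min=0.0)


def tree_signature(node):
    if node.is_leaf:
        return ("leaf", node.n, round(node.deviance, 8))
    return (
        node.split_var,
        round(node.split_threshold, 10),
        tree_signature(node.left),
        tree_signature(node.right),
    )


class TestBestSplit:
    def test_hand_example_single_response(self):
        var, thr, red = best_split(TOY_X, TOY_Y, LOOSE)
        assert var == 0
        assert thr == pytest.approx(6.5)
        assert red == pytest.approx(37.5)  # 6 * 2.5^2 -> 0

    def test_duplicated_response_column_doubles_reduction(self):
        var, thr, red = best_split(TOY_X, np.column_stack([TOY_Y, TOY_Y]), LOOSE)
        assert (var, thr) == (0, pytest.approx(6.5))
        assert red == pytest.approx(75.0)

    def test_constant_predictor_gives_none(self):
        X = np.full((6, 1), 3.0)
        assert best_split(X, TOY_Y, LOOSE) is None

    def test_constant_response_gives_none(self):
        assert best_split(TOY_X, np.zeros(6), LOOSE) is None

    def test_minbucket_respected(self):
        params = GrowthParams(minsplit=6, minbucket=3, cp_min=0.0)
        var, thr, red = best_split(TOY_X, TOY_Y, params)
        assert thr == pytest.approx(6.5)
        # only the 3|3 split satisfies minbucket=3 here
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        assert best_split(X, np.array([9.0, 0, 0, 0, 0]), params) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (8, 2))
        Y = rng.normal(0, 1, (8, 2))
        got = best_split(X, Y, LOOSE)

        # exhaustive oracle over every (var, midpoint)
        def ss(block):
            return float(((block - block.mean(axis=0)) ** 2).sum())

        best = None
        for j in range(X.shape[1]):
            vals = sorted(set(X[:, j]))
            for a, b in zip(vals, vals[1:]):
                thr = 0.5 * (a + b)
                mask = X[:, j] < thr
                red = ss(Y) - ss(Y[mask]) - ss(Y[~mask])
                if best is None or red > best[2] + 1e-12:
                    best = (j, thr, red)
        assert got[0] == best[0]
        assert got[1] == pytest.approx(best[1])
        assert got[2] == pytest.approx(best[2])


class TestGrowTree:
    def test_constant_response_single_leaf(self):
        tree = grow_tree(TOY_X, np.ones(6), LOOSE)
        assert tree.n_leaves == 1

    def test_two_separated_clusters_two_leaves(self, rng):
        n = 30
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, 3))
        X[:, 1] += labels * 12
        Y = labels * 8.0 + rng.normal(0, 0.3, n)
        tree = grow_tree(X, Y, GrowthParams(cp_min=0.01))
        assert tree.n_leaves == 2
        assert tree.root.split_var == "x1"

    def test_root_deviance_is_total_ss(self, rng):
        Y = rng.normal(0, 2, (20, 2))
        X = rng.normal(0, 1, (20, 3))
        tree = grow_tree(X, Y, GrowthParams())
        assert tree.root.deviance == pytest.approx(
            float(((Y - Y.mean(axis=0)) ** 2).sum())
        )

    def test_row_mismatch_rejected(self):
        with pytest.raises(CartError, match="rows"):
            grow_tree(TOY_X, np.zeros(5), LOOSE)

    def test_node_bookkeeping_invariants(self, rng):
        X = rng.normal(0, 1, (40, 3))
        Y = X[:, 0] * 2 + rng.normal(0, 0.5, 40)
        tree = grow_tree(X, Y, GrowthParams(minsplit=4, minbucket=2, cp_min=0.001))

        def check(node):
            if node.is_leaf:
                return
            assert node.n == node.left.n + node.right.n
            assert node.deviance >= node.left.deviance + node.right.deviance - 1e-9
            check(node.left)
            check(node.right)

        check(tree.root)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_small_fixtures(self, seed):
        """grow_tree with cp_min=0 equals brute-force enumeration (<=12 obs)."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 13))
        p = int(rng.integers(1, 4))
        X = np.round(rng.normal(0, 1, (n, p)), 2)
        Y = rng.normal(0, 1, (n, 2))
        params = GrowthParams(minsplit=2, minbucket=1, cp_min=0.0, max_depth=6)
        fast = grow_tree(X, Y, params)
        oracle = brute_force_tree(X, Y, params)
        assert tree_signature(fast.root) == tree_signature(oracle.root)

    def test_duplicated_response_column_same_splits(self, rng):
        X = rng.normal(0, 1, (30, 3))
        Y = rng.normal(0, 1, (30, 2))
        a = grow_tree(X, Y, GrowthParams(minsplit=6, minbucket=3, cp_min=0.01))
        b = grow_tree(
            X, np.hstack([Y, Y]), GrowthParams(minsplit=6, minbucket=3, cp_min=0.01)
        )

        def structure(node):
            if node.is_leaf:
                return ("leaf", node.n)
            return (
                node.split_var,
                round(node.split_threshold, 10),
                structure(node.left),
                structure(node.right),
            )

        assert structure(a.root) == structure(b.root)


class TestCpTable:
    def test_monotone_structure(self, rng):
        X = rng.normal(0, 1, (50, 3))
        Y = X[:, 0] * 3 + X[:, 1] + rng.normal(0, 0.4, 50)
        tree = grow_tree(X, Y, GrowthParams(minsplit=6, minbucket=3, cp_min=0.005))
        cps = [r[0] for r in tree.cp_table]
        leaves = [r[1] for r in tree.cp_table]
        rel = [r[2] for r in tree.cp_table]
        assert all(a > b for a, b in zip(cps, cps[1:]))
        assert all(a <= b for a, b in zip(leaves, leaves[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(rel, rel[1:]))
        assert rel[0] == pytest.approx(1.0)


class TestCvPrune:
    def test_single_leaf_passthrough(self):
        tree = grow_tree(TOY_X, np.ones(6), LOOSE)
        out = cv_prune_1se(tree, TOY_X, np.ones(6), LOOSE)
        assert out.n_leaves == 1

    def test_needs_enough_rows_for_folds(self):
        params = GrowthParams(minsplit=2, minbucket=1, cp_min=0.0, cv_folds=10)
        tree = grow_tree(TOY_X, TOY_Y, params)
        with pytest.raises(CartError, match="cv_folds"):
            cv_prune_1se(tree, TOY_X, TOY_Y, params)

    def test_seed_determinism(self, rng):
        X = rng.normal(0, 1, (40, 3))
        Y = X[:, 0] * 2 + rng.normal(0, 1, 40)
        params = GrowthParams(seed=42)
        t1 = cv_prune_1se(grow_tree(X, Y, params), X, Y, params)
        t2 = cv_prune_1se(grow_tree(X, Y, params), X, Y, params)
        assert t1.cp_table == t2.cp_table
        assert tree_signature(t1.root) == tree_signature(t2.root)

    def test_1se_never_larger_than_min_cv_tree(self, rng):
        X = rng.normal(0, 1, (60, 3))
        Y = np.column_stack([X[:, 0] * 3, X[:, 1]]) + rng.normal(0, 0.5, (60, 2))
        params = GrowthParams(seed=3)
        tree = grow_tree(X, Y, params)
        pruned = cv_prune_1se(tree, X, Y, params)
        risks = [r[3] for r in pruned.cp_table]
        k_min = int(np.argmin(risks))
        assert pruned.n_leaves <= pruned.cp_table[k_min][1]

    def test_planted_two_clusters_recovered(self):
        """Separation >> noise: the 1-SE tree finds exactly 2 leaves."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            n = 40
            labels = rng.integers(0, 2, n)
            X = rng.normal(0, 1, (n, 3))
            X[:, 0] += labels * 10
            Y = np.column_stack([labels * 5.0, labels * 3.0]) + rng.normal(
                0, 1, (n, 2)
            )
            params = GrowthParams(seed=seed)
            pruned = cv_prune_1se(grow_tree(X, Y, params), X, Y, params)
            hits += pruned.n_leaves == 2
        assert hits >= 90

    def test_pruned_is_subtree(self, rng):
        X = rng.normal(0, 1, (50, 3))
        Y = X[:, 0] * 4 + X[:, 2] + rng.normal(0, 0.3, 50)
        params = GrowthParams(seed=5, cp_min=0.001)
        full = grow_tree(X, Y, params)
        pruned = cv_prune_1se(full, X, Y, params)

        def is_subtree(sub, node):
            if sub.is_leaf:
                return True
            if node.is_leaf:
                return False
            return (
                sub.split_var == node.split_var
                and sub.split_threshold == pytest.approx(node.split_threshold)
                and is_subtree(sub.left, node.left)
                and is_subtree(sub.right, node.right)
            )

        assert is_subtree(pruned.root, full.root)


class TestAssignGroups:
    def test_single_leaf_all_group_one(self):
        tree = grow_tree(TOY_X, np.ones(6), LOOSE)
        assert list(assign_groups(tree, TOY_X)) == [1] * 6

    def test_toy_split_groups(self):
        tree = grow_tree(TOY_X, TOY_Y, LOOSE)
        # depth-first left-first numbering: below threshold first
        groups = assign_groups(tree, TOY_X)
        assert list(groups[:3]) != list(groups[3:])
        assert set(groups) == {1, 2}
        assert list(groups) == [1, 1, 1, 2, 2, 2]

    def test_partition_property(self, rng):
        X = rng.normal(0, 1, (30, 3))
        Y = X[:, 0] + rng.normal(0, 0.2, 30)
        tree = grow_tree(X, Y, GrowthParams(minsplit=6, minbucket=3, cp_min=0.01))
        groups = assign_groups(tree, X)
        assert len(groups) == 30
        assert set(groups) <= set(range(1, tree.n_leaves + 1))
        # every leaf is realized by its own training data
        assert len(set(groups)) == tree.n_leaves

    def test_missing_split_variable_rejected(self):
        tree = grow_tree(TOY_X, TOY_Y, LOOSE, var_names=("depth",))
        with pytest.raises(CartError, match="depth"):
            assign_groups(tree, TOY_X, var_names=("velocity",))

    def test_routing_by_name_with_extra_columns(self):
        tree = grow_tree(TOY_X, TOY_Y, LOOSE, var_names=("depth",))
        X2 = np.column_stack([np.zeros(6), TOY_X[:, 0]])
        groups = assign_groups(tree, X2, var_names=("junk", "depth"))
        assert list(groups) == [1, 1, 1, 2, 2, 2]


class TestGrowthParams:
    def test_invalid_minbucket(self):
        with pytest.raises(CartError):
            GrowthParams(minbucket=0)

    def test_minsplit_vs_minbucket(self):
        with pytest.raises(CartError):
            GrowthParams(minsplit=4, minbucket=3)
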