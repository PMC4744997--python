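"""Multivariate-response binary regression trees, implemented from scratch.

Growing is exhaustive recursive partitioning on predictor thresholds,
minimizing the within-node sum of squared deviations summed over all
response columns.  Pruning follows the classical cost-complexity
(weakest-link) construction; the final tree size is chosen by K-fold
cross-validation with the 1-SE rule.

Deviances in the complexity table are normalized by the root deviance,
so ``cp`` values are relative improvements, matching standard practice.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


class CartError(ValueError):
    pass


@dataclass
class GrowthParams:
    """Tree-growing and pruning controls.

    Defaults are scaled to assemblages of a few dozen species rather
    than the larger samples the classical defaults assume.
    """

    minsplit: int = 10
    minbucket: int = 3
    cp_min: float = 0.01
    max_depth: int = 10
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.minbucket < 1:
            raise CartError("minbucket must be >= 1")
        if self.minsplit < 2 * self.minbucket:
            raise CartError("minsplit must be >= 2*minbucket")


@dataclass
class TreeNode:
    """One node of a regression tree.

    ``split_var``/``split_threshold`` are None for leaves; observations
    with predictor value strictly below the threshold go left.
    """

    n: int
    response_mean: np.ndarray
    deviance: float
    split_var: str | None = None
    split_var_idx: int | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def subtree_deviance(self) -> float:
        return sum(leaf.deviance for leaf in self.leaves())

    def route(self, x: np.ndarray) -> "TreeNode":
        node = self
        while not node.is_leaf:
            if x[node.split_var_idx] < node.split_threshold:
                node = node.left
            else:
                node = node.right
        return node

    def outline(self, depth: int = 0) -> str:
        pad = "  " * depth
        if self.is_leaf:
            return f"{pad}leaf n={self.n} dev={self.deviance:.6g}"
        head = (
            f"{pad}{self.split_var} < {self.split_threshold:.6g} "
            f"n={self.n} dev={self.deviance:.6g}"
        )
        return "\n".join(
            [head, self.left.outline(depth + 1), self.right.outline(depth + 1)]
        )


@dataclass
class RegressionTree:
    root: TreeNode
    params: GrowthParams
    var_names: tuple
    # rows: (cp, n_leaves, rel training error, CV mean, CV SE); CV columns
    # are NaN until cv_prune_1se fills them in
    cp_table: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.vstack([self.root.route(row).response_mean for row in X])

    def outline(self) -> str:
        return self.root.outline()


def _node_stats(Y: np.ndarray):
    mean = Y.mean(axis=0)
    dev = float(((Y - mean) ** 2).sum())
    return mean, dev


def best_split(X: np.ndarray, Y: np.ndarray, params: GrowthParams, var_names=None):
    """Exhaustive best single split at a node.

    Scans every predictor and every midpoint between consecutive
    distinct sorted values, maximizing the reduction in total
    within-node SS summed across response columns; honours
    ``minbucket``.  Returns ``(var_idx, threshold, reduction)`` or
    ``None`` when no admissible split exists.  Ties go to the lower
    predictor index, then the lower threshold.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 2 * params.minbucket:
        return None
    _, dev_total = _node_stats(Y)
    tol = 1e-10 * max(1.0, dev_total)
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = Y[order]
        csum = np.cumsum(ys, axis=0)
        csq = np.cumsum(ys**2, axis=0)
        tot_sum = csum[-1]
        tot_sq = csq[-1]
        for i in range(params.minbucket, n - params.minbucket + 1):
            if i > n - params.minbucket or xs[i - 1] == xs[i]:
                continue
            nl, nr = i, n - i
            ss_l = float((csq[i - 1] - csum[i - 1] ** 2 / nl).sum())
            ss_r = float(((tot_sq - csq[i - 1]) - (tot_sum - csum[i - 1]) ** 2 / nr).sum())
            red = dev_total - ss_l - ss_r
            if best is None or red > best[2] + tol:
                thr = 0.5 * (xs[i - 1] + xs[i])
                best = (j, float(thr), red)
    if best is None or best[2] <= tol:
        return None
    return best


def grow_tree(X: np.ndarray, Y: np.ndarray, params: GrowthParams, var_names=None) -> RegressionTree:
    """Grow a full tree by recursive partitioning.

    Splitting stops when a node has fewer than ``minsplit`` rows,
    ``max_depth`` is reached, or the best split improves total deviance
    by less than ``cp_min`` times the root deviance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise CartError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if var_names is None:
        var_names = tuple(f"x{j}" for j in range(X.shape[1]))
    var_names = tuple(var_names)
    _, root_dev = _node_stats(Y)
    threshold = params.cp_min * root_dev

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        mean, dev = _node_stats(Y[rows])
        node = TreeNode(n=len(rows), response_mean=mean, deviance=dev)
        if len(rows) < params.minsplit or depth >= params.max_depth:
            return node
        found = best_split(X[rows], Y[rows], params)
        if found is None or found[2] < threshold:
            return node
        j, thr, _ = found
        mask = X[rows, j] < thr
        node.split_var = var_names[j]
        node.split_var_idx = j
        node.split_threshold = thr
        node.left = build(rows[mask], depth + 1)
        node.right = build(rows[~mask], depth + 1)
        return node

    root = build(np.arange(X.shape[0]), 0)
    tree = RegressionTree(root, params, var_names)
    tree.cp_table = _complexity_table(tree)
    return tree


def _weakest_link_sequence(root: TreeNode):
    """Cost-complexity sequence: list of (alpha, tree) with trees shrinking.

    alpha values are absolute deviances; the first entry is the full
    tree at alpha 0 and the last is the root-only tree.
    """
    tree = copy.deepcopy(root)
    seq = [(0.0, copy.deepcopy(tree))]
    while not tree.is_leaf:
        # g(t) = (R(t) - R(T_t)) / (|leaves(T_t)| - 1) for internal t
        internal = []

        def collect(node):
            if not node.is_leaf:
                g = (node.deviance - node.subtree_deviance()) / (node.n_leaves - 1)
                internal.append((g, node))
                collect(node.left)
                collect(node.right)

        collect(tree)
        g_min = min(g for g, _ in internal)
        for g, node in internal:
            if g <= g_min + 1e-12 * max(1.0, abs(g_min)):
                node.left = node.right = None
                node.split_var = node.split_var_idx = node.split_threshold = None
        seq.append((max(g_min, 0.0), copy.deepcopy(tree)))
    return seq


def _prune_at(seq, alpha: float) -> TreeNode:
    """Smallest tree in the sequence optimal for complexity ``alpha``."""
    best = seq[0][1]
    for a, t in seq:
        if a <= alpha + 1e-15:
            best = t
    return best


def _complexity_table(tree: RegressionTree):
    root_dev = tree.root.deviance
    if root_dev == 0:
        return [(tree.params.cp_min, 1, 0.0, float("nan"), float("nan"))]
    seq = _weakest_link_sequence(tree.root)
    rows = []
    for k, (alpha, t) in enumerate(seq):
        if k + 1 < len(seq) and seq[k + 1][0] <= alpha + 1e-15:
            continue  # collapse duplicate alphas
        cp = tree.params.cp_min if k == 0 else alpha / root_dev
        rows.append((cp, t.n_leaves, t.subtree_deviance() / root_dev, float("nan"), float("nan")))
    rows.sort(key=lambda r: (-r[0], r[1]))
    # enforce strictly decreasing cp
    dedup = []
    for r in rows:
        if dedup and r[0] >= dedup[-1][0] - 1e-15:
            dedup[-1] = r if r[1] >= dedup[-1][1] else dedup[-1]
        else:
            dedup.append(r)
    return dedup


def cv_prune_1se(tree: RegressionTree, X: np.ndarray, Y: np.ndarray,
                 params: GrowthParams | None = None) -> RegressionTree:
    """Prune by K-fold cross-validated cost-complexity with the 1-SE rule.

    For each candidate complexity (geometric means of adjacent cp values
    of the main tree), trees grown on each training fold are pruned to
    that complexity and used to predict the held-out rows.  The selected
    tree is the smallest one whose CV error is within one standard error
    of the minimum.  Fold assignment is a seeded random permutation, so
    the result is deterministic given ``params.seed``.
    """
    if params is None:
        params = tree.params
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if tree.root.is_leaf:
        return tree
    if n < params.cv_folds:
        raise CartError(
            f"n={n} < cv_folds={params.cv_folds}; reduce cv_folds"
        )
    root_dev = tree.root.deviance
    main_seq = _weakest_link_sequence(tree.root)
    table = [list(r) for r in tree.cp_table or _complexity_table(tree)]
    cps = [r[0] for r in table]  # strictly decreasing
    # evaluation complexities: geometric means of adjacent cps
    betas = []
    for k in range(len(cps)):
        if k == 0:
            betas.append(cps[0])
        else:
            betas.append(float(np.sqrt(cps[k - 1] * max(cps[k], 1e-30))))

    rng = np.random.default_rng(params.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, params.cv_folds)
    errs = np.zeros((len(betas), n))  # per-observation held-out SS
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        sub = grow_tree(X[train], Y[train], params, tree.var_names)
        sub_seq = _weakest_link_sequence(sub.root)
        sub_root_dev = sub.root.deviance
        for k, beta in enumerate(betas):
            pruned = _prune_at(sub_seq, beta * sub_root_dev)
            for i in fold:
                pred = pruned.route(X[i]).response_mean
                errs[k, i] = float(((Y[i] - pred) ** 2).sum())
    risk = errs.sum(axis=1) / root_dev
    se = np.sqrt(n) * errs.std(axis=1, ddof=1) / root_dev
    k_min = int(np.argmin(risk))
    limit = risk[k_min] + se[k_min]
    k_sel = next(k for k in range(len(betas)) if risk[k] <= limit + 1e-12)
    for k, row in enumerate(table):
        row[3], row[4] = float(risk[k]), float(se[k])
    # main-sequence tree whose size matches the selected cp row
    target_leaves = table[k_sel][1]
    pruned_root = next(t for _, t in main_seq if t.n_leaves == target_leaves)
    out = RegressionTree(copy.deepcopy(pruned_root), params, tree.var_names)
    out.cp_table = [tuple(r) for r in table]
    return out


def assign_groups(tree: RegressionTree, X: np.ndarray, var_names=None) -> np.ndarray:
    """Route every row to a leaf; leaves numbered 1..n_leaves DFS left-first.

    Left children (below threshold) are numbered before right children,
    matching the dendrogram reading order of the niche codes.
    """
    X = np.asarray(X, dtype=float)
    if var_names is None:
        col = {v: i for i, v in enumerate(tree.var_names)}
    else:
        col = {v: i for i, v in enumerate(var_names)}
    missing = {
        node.split_var
        for node in _internal_nodes(tree.root)
        if node.split_var not in col
    }
    if missing:
        raise CartError(f"predictors missing from X: {sorted(missing)}")
    leaf_ids = {id(leaf): g + 1 for g, leaf in enumerate(tree.root.leaves())}

    def route(row):
        node = tree.root
        while not node.is_leaf:
            if row[col[node.split_var]] < node.split_threshold:
                node = node.left
            else:
                node = node.right
        return node

    return np.array([leaf_ids[id(route(row))] for row in X], dtype=int)


def _internal_nodes(node: TreeNode):
    if node.is_leaf:
        return []
    return [node] + _internal_nodes(node.left) + _internal_nodes(node.right)


def brute_force_tree(X, Y, params: GrowthParams, var_names=None) -> RegressionTree:
    """Independent exhaustive-search reference grower (test oracle).

    Enumerates every (variable, midpoint) candidate directly, without
    the prefix-sum optimization, and recurses with the same stopping
    rules as :func:`grow_tree`.  Kept deliberately naive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if var_names is None:
        var_names = tuple(f"x{j}" for j in range(X.shape[1]))

    def ss(block):
        return float(((block - block.mean(axis=0)) ** 2).sum())

    root_dev = ss(Y)
    tol = 1e-10 * max(1.0, root_dev)

    def search(rows):
        dev = ss(Y[rows])
        best = None
        for j in range(X.shape[1]):
            vals = sorted(set(X[rows, j]))
            for a, b in zip(vals, vals[1:]):
                thr = 0.5 * (a + b)
                mask = X[rows, j] < thr
                nl, nr = int(mask.sum()), int((~mask).sum())
                if nl < params.minbucket or nr < params.minbucket:
                    continue
                red = dev - ss(Y[rows[mask]]) - ss(Y[rows[~mask]])
                if best is None or red > best[2] + 1e-10 * max(1.0, dev):
                    best = (j, thr, red)
        return best

    def build(rows, depth):
        mean = Y[rows].mean(axis=0)
        node = TreeNode(n=len(rows), response_mean=mean, deviance=ss(Y[rows]))
        if len(rows) < params.minsplit or depth >= params.max_depth:
            return node
        found = search(rows)
        if found is None or found[2] <= tol or found[2] < params.cp_min * root_dev:
            return node
        j, thr, _ = found
        mask = X[rows, j] < thr
        node.split_var, node.split_var_idx, node.split_threshold = var_names[j], j, thr
        node.left = build(rows[mask], depth + 1)
        node.right = build(rows[~mask], depth + 1)
        return node

    tree = RegressionTree(build(np.arange(X.shape[0]), 0), params, tuple(var_names))
    tree.cp_table = _complexity_table(tree)
    return tree
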