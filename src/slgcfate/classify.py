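"""Behaviour prediction: Gini CART with cost-complexity pruning.

A from-scratch classification tree in the CART style: binary splits on
numeric features chosen to maximise the decrease in weighted Gini
impurity, grown to purity (or a minimum leaf size), then pruned along
the minimal cost-complexity ("weakest link") path.  The pruning level
(ccp_alpha) is chosen to maximise accuracy on a held-out 30% split.
Bagged-forest feature importances (normalised total Gini decrease) use
the same tree grower with bootstrap resampling and sqrt(d) feature
subsampling per split.

Conventions (fixed and tested):

* splits are ``feature <= t`` with t the midpoint of adjacent sorted
  unique values; a row exactly at t routes left (the <= branch);
* a class tie at a leaf predicts ACD;
* equal-accuracy pruning levels resolve to the larger alpha (the
  smaller tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ACD, DIFF, UNKNOWN

__all__ = [
    "CLASSES",
    "gini_impurity",
    "TreeNode",
    "PruningPath",
    "CartResult",
    "fit_cart",
    "grow_tree",
    "pruning_path",
    "predict_cart",
    "tree_accuracy",
    "forest_importances",
    "tree_to_dict",
]

#: Class order; argmax tie-breaking makes ACD the tie winner everywhere.
CLASSES = (ACD, DIFF)

_MIN_DECREASE = 1e-12


def gini_impurity(class_probabilities) -> float:
    """Gini impurity of a class distribution: sum_i p_i * (1 - p_i).

    For two classes this is 2 p (1 - p), maximal (0.5) at p = 0.5 and 0
    for a pure node.  Probabilities must be non-negative and sum to 1
    within 1e-9.
    """
    p = np.asarray(class_probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    return float(np.sum(p * (1.0 - p)))


def _counts_gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(np.sum(p * (1.0 - p)))


@dataclass
class TreeNode:
    """One node of the classification tree.

    Internal nodes carry a (feature, threshold) split; rows with
    ``feature <= threshold`` go left.  ``counts`` are training class
    counts in :data:`CLASSES` order and always equal the sum over the
    children of an internal node.
    """

    counts: np.ndarray
    impurity: float
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> str:
        return CLASSES[int(np.argmax(self.counts))]

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def copy(self) -> "TreeNode":
        return TreeNode(
            counts=self.counts.copy(),
            impurity=self.impurity,
            feature=self.feature,
            threshold=self.threshold,
            left=None if self.left is None else self.left.copy(),
            right=None if self.right is None else self.right.copy(),
        )


def _best_split(
    X: np.ndarray, y: np.ndarray, feature_idx: Sequence[int], min_leaf: int
):
    """Best (feature index, threshold, weighted child impurity) or None.

    Scans all midpoints between distinct adjacent sorted values of each
    candidate feature; vectorised per feature.  Ties keep the first
    candidate encountered (feature order, then smallest threshold).
    """
    n = y.size
    total1 = int(y.sum())
    best = None
    best_impurity = np.inf
    for j in feature_idx:
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cum1 = np.cumsum(ys)
        i = np.arange(1, n)  # left set = first i rows
        valid = xs[1:] > xs[:-1]
        if min_leaf > 1:
            valid &= (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        n1l = cum1[:-1]
        n0l = i - n1l
        n1r = total1 - n1l
        n0r = (n - i) - n1r
        gl = 1.0 - (n0l**2 + n1l**2) / i**2
        gr = 1.0 - (n0r**2 + n1r**2) / (n - i) ** 2
        weighted = (i * gl + (n - i) * gr) / n
        weighted = np.where(valid, weighted, np.inf)
        k = int(np.argmin(weighted))
        if weighted[k] < best_impurity - 1e-15:
            best_impurity = float(weighted[k])
            best = (j, float(0.5 * (xs[k] + xs[k + 1])), best_impurity)
    return best


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    min_leaf: int = 1,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow a tree to purity (or ``min_leaf``) by greedy Gini splits.

    ``y`` holds class indices into :data:`CLASSES`.  With
    ``max_features`` set, each split considers a random feature subset
    (used by the bagged forest).  A node becomes a leaf when no split
    strictly decreases weighted impurity.
    """
    counts = np.bincount(y, minlength=len(CLASSES)).astype(float)
    node = TreeNode(counts=counts, impurity=_counts_gini(counts))
    if node.impurity == 0.0 or y.size < 2 * min_leaf:
        return node
    d = X.shape[1]
    if max_features is not None and max_features < d:
        assert rng is not None, "feature subsampling requires an rng"
        candidates = rng.choice(d, size=max_features, replace=False)
        candidates.sort()
    else:
        candidates = range(d)
    best = _best_split(X, y, candidates, min_leaf)
    if best is None:
        return node
    j, threshold, weighted = best
    if node.impurity - weighted <= _MIN_DECREASE:
        return node
    mask = X[:, j] <= threshold
    node.feature = feature_names[j]
    node.threshold = threshold
    node.left = grow_tree(X[mask], y[mask], feature_names, min_leaf, max_features, rng)
    node.right = grow_tree(X[~mask], y[~mask], feature_names, min_leaf, max_features, rng)
    return node


# ---------------------------------------------------------------------------
# Minimal cost-complexity (weakest-link) pruning


@dataclass
class PruningPath:
    """The weakest-link pruning sequence of a grown tree.

    ``alphas`` are the effective complexity parameters (strictly
    increasing, starting at 0 for the full tree); ``trees`` the
    corresponding pruned subtrees; ``n_leaves`` their leaf counts
    (strictly decreasing to 1).  ``test_accuracy`` is filled by
    :func:`fit_cart`.
    """

    alphas: list[float] = field(default_factory=list)
    trees: list[TreeNode] = field(default_factory=list)
    n_leaves: list[int] = field(default_factory=list)
    test_accuracy: list[float] | None = None


def _subtree_stats(node: TreeNode, n_total: int):
    """(R_subtree, n_leaves) where R sums (n_t / N) * gini over leaves."""
    if node.is_leaf:
        return (node.n / n_total) * node.impurity, 1
    rl, ll = _subtree_stats(node.left, n_total)
    rr, lr = _subtree_stats(node.right, n_total)
    return rl + rr, ll + lr


def _weakest_links(node: TreeNode, n_total: int, out: list):
    """Collect (g(t), node) for every internal node t."""
    if node.is_leaf:
        return
    r_sub, leaves = _subtree_stats(node, n_total)
    r_node = (node.n / n_total) * node.impurity
    out.append(((r_node - r_sub) / (leaves - 1), node))
    _weakest_links(node.left, n_total, out)
    _weakest_links(node.right, n_total, out)


def pruning_path(tree: TreeNode) -> PruningPath:
    """Minimal cost-complexity pruning path of a grown tree.

    Repeatedly collapses the internal node(s) with the smallest
    effective alpha g(t) = (R(t) - R(T_t)) / (|leaves(T_t)| - 1), where R
    is the sample-weighted Gini risk, until only the root remains.
    """
    n_total = tree.n
    work = tree.copy()
    path = PruningPath()
    path.alphas.append(0.0)
    path.trees.append(work.copy())
    path.n_leaves.append(work.n_leaves())
    while not work.is_leaf:
        links: list = []
        _weakest_links(work, n_total, links)
        alpha = min(g for g, _ in links)
        for g, node in links:
            # collapse every node attaining the minimum (within fp jitter)
            if g <= alpha + 1e-15 and not node.is_leaf:
                node.left = node.right = None
                node.feature = node.threshold = None
        alpha = float(alpha)
        if alpha <= path.alphas[-1] and len(path.alphas) > 1:
            # tied effective alpha: merge into the previous step so the
            # recorded alphas stay strictly increasing
            path.trees[-1] = work.copy()
            path.n_leaves[-1] = work.n_leaves()
        else:
            path.alphas.append(alpha)
            path.trees.append(work.copy())
            path.n_leaves.append(work.n_leaves())
    return path


def predict_cart(tree: TreeNode, row: Mapping[str, float]) -> str:
    """Route one feature row to a leaf; returns the leaf's majority class.

    Routing is deterministic with the half-open convention: a value
    exactly at a threshold goes to the <= (left) branch.
    """
    node = tree
    while not node.is_leaf:
        if node.feature not in row:
            raise KeyError(f"row is missing feature {node.feature!r}")
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.prediction


def _predict_matrix(tree: TreeNode, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    idx = {f: i for i, f in enumerate(feature_names)}
    out = np.empty(X.shape[0], dtype=int)
    for r in range(X.shape[0]):
        node = tree
        while not node.is_leaf:
            node = node.left if X[r, idx[node.feature]] <= node.threshold else node.right
        out[r] = int(np.argmax(node.counts))
    return out


def tree_accuracy(tree: TreeNode, X: np.ndarray, y: np.ndarray, feature_names) -> float:
    return float(np.mean(_predict_matrix(tree, X, feature_names) == y))


@dataclass
class CartResult:
    """Fitted, pruned tree with its pruning path and held-out accuracy."""

    tree: TreeNode
    path: PruningPath
    ccp_alpha: float
    test_accuracy: float
    features: tuple[str, ...]
    n_train: int
    n_test: int


def _prepare(table: pd.DataFrame, features, target: str):
    df = table[table[target] != UNKNOWN]
    if features is None:
        exclude = {target, "cell_id", "individual", "mother_id"}
        features = [
            c
            for c in df.columns
            if c not in exclude and pd.api.types.is_numeric_dtype(df[c])
        ]
    if not features:
        raise ValueError("no numeric features to split on")
    bad = set(df[target]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown behaviour label(s): {sorted(bad)}")
    X = df[list(features)].to_numpy(dtype=float)
    y = df[target].map({c: i for i, c in enumerate(CLASSES)}).to_numpy(dtype=int)
    return X, y, tuple(features)


def fit_cart(
    table: pd.DataFrame,
    features: Sequence[str] | None = None,
    target: str = "behaviour",
    split_ratio: float = 0.7,
    seed: int = 0,
    min_leaf: int = 1,
) -> CartResult:
    """Fit and prune a behaviour-prediction tree with a held-out split.

    Rows labelled UNKNOWN are excluded.  The table is split
    train:test = ``split_ratio`` : rest by seeded random sampling without
    replacement (not stratified); the tree is grown to purity on the
    training part, the cost-complexity path is computed, every subtree is
    scored on the test part, and the subtree at the accuracy-maximising
    alpha is returned (ties resolve to the larger alpha, i.e. the
    smaller tree).  Single-class data yields a degenerate one-leaf tree.
    """
    X, y, features = _prepare(table, features, target)
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 labelled rows, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_ratio * n))
    train, test = perm[:n_train], perm[n_train:]
    full = grow_tree(X[train], y[train], features, min_leaf=min_leaf)
    path = pruning_path(full)
    path.test_accuracy = [
        tree_accuracy(t, X[test], y[test], features) for t in path.trees
    ]
    best_acc = max(path.test_accuracy)
    # ties -> larger alpha (parsimony); alphas increase along the path
    best_idx = max(i for i, a in enumerate(path.test_accuracy) if a == best_acc)
    return CartResult(
        tree=path.trees[best_idx],
        path=path,
        ccp_alpha=path.alphas[best_idx],
        test_accuracy=best_acc,
        features=features,
        n_train=int(train.size),
        n_test=int(test.size),
    )


def forest_importances(
    table: pd.DataFrame,
    features: Sequence[str] | None = None,
    target: str = "behaviour",
    n_trees: int = 1000,
    seed: int = 0,
    min_leaf: int = 1,
) -> pd.Series:
    """Bagged-forest feature importances.

    Fits ``n_trees`` trees to bootstrap resamples with sqrt(d) feature
    subsampling per split and sums, per feature, the sample-weighted Gini
    decrease of every split made on it; the result is normalised to sum
    to 1.  An all-pure target (no splits anywhere) yields all-zero
    scores.
    """
    X, y, features = _prepare(table, features, target)
    n, d = X.shape
    if n < 10:
        raise ValueError(f"need >= 10 labelled rows, got {n}")
    max_features = max(1, int(round(math.sqrt(d))))
    rng = np.random.default_rng(seed)
    totals = np.zeros(d)
    index = {f: i for i, f in enumerate(features)}

    def accumulate(node: TreeNode, n_tree: int):
        if node.is_leaf:
            return
        decrease = (
            node.n * node.impurity
            - node.left.n * node.left.impurity
            - node.right.n * node.right.impurity
        ) / n_tree
        totals[index[node.feature]] += decrease
        accumulate(node.left, n_tree)
        accumulate(node.right, n_tree)

    for _ in range(n_trees):
        rows = rng.integers(0, n, n)
        tree = grow_tree(
            X[rows], y[rows], features, min_leaf=min_leaf,
            max_features=max_features, rng=rng,
        )
        accumulate(tree, n)
    total = totals.sum()
    if total > 0:
        totals = totals / total
    return pd.Series(totals, index=list(features), name="importance")


def tree_to_dict(node: TreeNode) -> dict:
    """Nested-dict form of a tree for JSON serialisation."""
    d = {
        "counts": {c: int(k) for c, k in zip(CLASSES, node.counts)},
        "impurity": node.impurity,
        "prediction": node.prediction,
    }
    if not node.is_leaf:
        d.update(
            feature=node.feature,
            threshold=node.threshold,
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d
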