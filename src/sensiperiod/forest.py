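"""Conditional inference trees and forests with permutation variable importance.

The base learner chooses its split variable by a rank-based association test
rather than by impurity reduction.  At every node a random subset of ``mtry``
candidate features is drawn; for each candidate the standardized linear
association statistic between the (mid-ranked) feature and the response
scores is computed, and its two-sided asymptotic p-value is Bonferroni
adjusted over the candidates.  If no candidate is significant at
``alpha_split`` the node becomes a leaf; otherwise the most significant
feature is split at the cutpoint maximizing the standardized two-sample
statistic.  Because variable selection is a rank test decoupled from the
split search, it is not biased toward features with many distinct values,
wide ranges, or large variances — the property that motivates using this
learner on highly collinear, mixed-granularity exposure data.

Variable importance is the Breiman-style permutation scheme: for each tree,
performance on the tree's own out-of-subsample rows is compared before and
after permuting one feature column, and the degradation is averaged over
trees.  Features never used by a tree contribute exactly zero for that tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from ._rng import splitmix64

__all__ = [
    "ForestConfig",
    "Tree",
    "ForestModel",
    "fit_tree",
    "fit_forest",
    "predict",
    "predict_proba",
    "permutation_importance",
]


@dataclass
class ForestConfig:
    """Settings for tree induction and the forest ensemble.

    mtry defaults to ceil(sqrt(p)) at fit time when left as None.
    ``min_node`` is the smallest node that may still be split; every child
    must receive at least ``min_child`` rows.  Subsamples are drawn without
    replacement.
    """

    n_trees: int = 500
    mtry: Optional[int] = None
    alpha_split: float = 0.05
    min_node: int = 7
    min_child: int = 3
    subsample_fraction: float = 0.632
    n_permutations: int = 5
    max_depth: int = 30

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return min(int(self.mtry), n_features)
        return min(int(np.ceil(np.sqrt(n_features))), n_features)

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.alpha_split <= 1.0:
            raise ValueError("alpha_split must be in (0, 1]")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if self.min_child < 1:
            raise ValueError("min_child must be >= 1")


@dataclass
class Tree:
    """Flat array representation of a fitted tree.

    ``feature[i] == -1`` marks a leaf; ``value`` holds the leaf mean
    response (regression) or the leaf probability of class 1
    (classification).  ``threshold`` splits as ``x <= threshold -> left``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_node: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    def used_features(self) -> np.ndarray:
        f = self.feature[self.feature >= 0]
        return np.unique(f)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorized root-to-leaf traversal."""
        idx = np.zeros(X.shape[0], dtype=np.intp)
        feature = self.feature
        while True:
            f = feature[idx]
            internal = f >= 0
            if not internal.any():
                break
            rows = np.flatnonzero(internal)
            fr = f[rows]
            go_left = X[rows, fr] <= self.threshold[idx[rows]]
            idx[rows] = np.where(go_left, self.left[idx[rows]], self.right[idx[rows]])
        return self.value[idx]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "n_node": self.n_node.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            value=np.asarray(d["value"], dtype=float),
            n_node=np.asarray(d["n_node"], dtype=np.intp),
        )


@dataclass
class ForestModel:
    trees: list
    subsample_indices: list
    config: ForestConfig
    task: str  # "classification" | "regression"
    n_features: int
    seed: int
    feature_names: Optional[list] = None
    _train_shape: tuple = field(default=(0, 0))

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "task": self.task,
            "seed": self.seed,
            "n_features": self.n_features,
            "feature_names": self.feature_names,
            "config": {
                "n_trees": self.config.n_trees,
                "mtry": self.config.mtry,
                "alpha_split": self.config.alpha_split,
                "min_node": self.config.min_node,
                "min_child": self.config.min_child,
                "subsample_fraction": self.config.subsample_fraction,
                "n_permutations": self.config.n_permutations,
                "max_depth": self.config.max_depth,
            },
            "subsample_indices": [s.tolist() for s in self.subsample_indices],
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        cfg = ForestConfig(**d["config"])
        return cls(
            trees=[Tree.from_dict(t) for t in d["trees"]],
            subsample_indices=[np.asarray(s, dtype=np.intp) for s in d["subsample_indices"]],
            config=cfg,
            task=d["task"],
            n_features=d["n_features"],
            seed=d["seed"],
            feature_names=d.get("feature_names"),
        )


# ---------------------------------------------------------------------------
# association statistic


def _midranks(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def _assoc_z(h: np.ndarray, g_centered: np.ndarray, g_ss: float) -> float:
    """Standardized linear statistic: corr(h, g) * sqrt(n-1).

    Equals the standardized rank-sum statistic when g is a binary indicator
    and h holds midranks, and a Spearman-type statistic when g holds
    response midranks.  Tie structure enters through the midranks.
    """
    n = h.size
    hc = h - h.mean()
    h_ss = float(hc @ hc)
    if h_ss <= 0.0 or g_ss <= 0.0:
        return 0.0
    r = float(hc @ g_centered) / np.sqrt(h_ss * g_ss)
    r = min(1.0, max(-1.0, r))
    return r * np.sqrt(n - 1.0)


def _candidate_features(tree_key: int, node_path_hash: int, p: int, mtry: int) -> np.ndarray:
    """mtry candidate features for one node, by stateless hashed priorities.

    Every (tree, node, feature) triple receives an independent 64-bit
    priority; the mtry smallest win.  Priorities of existing features do not
    depend on the total feature count, so appending a new feature leaves
    candidate draws of the original features untouched wherever the new
    feature does not itself enter the candidate set.
    """
    if mtry >= p:
        return np.arange(p, dtype=np.intp)
    idx = np.arange(p, dtype=np.uint64)
    key = splitmix64(np.uint64(tree_key) ^ splitmix64(np.uint64(node_path_hash)))
    prio = splitmix64(idx ^ np.uint64(key))
    cand = np.argpartition(prio, mtry)[:mtry]
    return np.sort(cand).astype(np.intp)


def _best_cutpoint(
    x: np.ndarray, g: np.ndarray, min_child: int
) -> Optional[tuple]:
    """Cutpoint maximizing the standardized two-sample statistic.

    For every admissible boundary between distinct observed values of x, the
    statistic is |S_L - E[S_L]| / sd(S_L), where S_L is the sum of response
    scores g in the left group, with moments taken under the permutation
    null.  Ties break toward the smallest cutpoint.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gs = g[order]
    gbar = gs.mean()
    g_ss = float(np.sum((gs - gbar) ** 2))
    if g_ss <= 0.0:
        return None
    csum = np.cumsum(gs)
    n_left = np.arange(1, n)  # boundary after position i -> n_left = i+1
    valid = (xs[:-1] < xs[1:]) & (n_left >= min_child) & (n - n_left >= min_child)
    if not valid.any():
        return None
    s_left = csum[:-1]
    e_left = n_left * gbar
    var_left = n_left * (n - n_left) * g_ss / (n * (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zc = np.abs(s_left - e_left) / np.sqrt(var_left)
    zc = np.where(valid, zc, -np.inf)
    best = int(np.argmax(zc))  # argmax takes first max -> smallest cutpoint
    if not np.isfinite(zc[best]):
        return None
    return float(xs[best]), float(zc[best])


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig,
    task: str,
    tree_key: int = 0,
) -> Tree:
    """Grow one conditional inference tree on (X, y).

    ``tree_key`` seeds the per-node candidate-feature draws; two calls with
    identical data, config and key produce identical trees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    n, p = X.shape
    if n < 1 or p < 1:
        raise ValueError("need at least one row and one feature")
    mtry = config.resolved_mtry(p)

    feature: list = []
    threshold: list = []
    left: list = []
    right: list = []
    value: list = []
    n_node: list = []

    def leaf_value(rows: np.ndarray) -> float:
        return float(y[rows].mean())

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        n_node.append(0)
        return len(feature) - 1

    min_split = max(config.min_node, 2 * config.min_child)
    root = new_node()
    # stack of (node_id, row_indices, path_hash, depth); path hashes are
    # stable per root-to-node path, so candidate draws do not depend on
    # traversal order elsewhere in the tree
    stack = [(root, np.arange(n, dtype=np.intp), np.uint64(0x243F6A8885A308D3), 0)]
    while stack:
        node, rows, path_hash, depth = stack.pop()
        m = rows.size
        n_node[node] = m
        value[node] = leaf_value(rows)
        if m < min_split or depth >= config.max_depth:
            continue
        if task == "classification":
            g = y[rows]
        else:
            g = _midranks(y[rows])
        gbar = g.mean()
        gc = g - gbar
        g_ss = float(gc @ gc)
        if g_ss <= 0.0:
            continue  # constant response
        cand = _candidate_features(tree_key, int(path_hash), p, mtry)
        zs = np.empty(cand.size)
        for k, j in enumerate(cand):
            zs[k] = _assoc_z(_midranks(X[rows, j]), gc, g_ss)
        k_best = int(np.argmax(np.abs(zs)))  # ties -> lowest feature index
        z_best = abs(zs[k_best])
        # Bonferroni-adjusted two-sided asymptotic p over the candidates
        p_adj = min(1.0, 2.0 * float(ndtr(-z_best)) * cand.size)
        if p_adj >= config.alpha_split:
            continue
        j_split = int(cand[k_best])
        cut = _best_cutpoint(X[rows, j_split], g, config.min_child)
        if cut is None:
            continue
        thr, _ = cut
        go_left = X[rows, j_split] <= thr
        rows_l = rows[go_left]
        rows_r = rows[~go_left]
        if rows_l.size < config.min_child or rows_r.size < config.min_child:
            continue
        feature[node] = j_split
        threshold[node] = thr
        nl = new_node()
        nr = new_node()
        left[node] = nl
        right[node] = nr
        h_l = splitmix64(path_hash ^ np.uint64(0x9E3779B97F4A7C15))
        h_r = splitmix64(path_hash ^ np.uint64(0xC2B2AE3D27D4EB4F))
        stack.append((nl, rows_l, np.uint64(h_l), depth + 1))
        stack.append((nr, rows_r, np.uint64(h_r), depth + 1))

    return Tree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        value=np.asarray(value, dtype=float),
        n_node=np.asarray(n_node, dtype=np.intp),
    )


def _infer_task(y: np.ndarray) -> str:
    vals = np.unique(y)
    if vals.size <= 2 and np.isin(vals, [0.0, 1.0]).all():
        return "classification"
    return "regression"


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[ForestConfig] = None,
    seed: int = 0,
    task: Optional[str] = None,
    feature_names: Optional[list] = None,
) -> ForestModel:
    """Fit a conditional inference forest.

    Each tree is grown on an independent subsample drawn without replacement
    (``subsample_fraction`` of the rows).  Binary classification expects a
    0/1 response; anything else is treated as regression.
    """
    config = config or ForestConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-d with one row per response value")
    n, p = X.shape
    if task is None:
        task = _infer_task(y)
    if task == "classification":
        vals = np.unique(y)
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("classification response must be coded 0/1")

    root_ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    rows_ss, key_ss = root_ss.spawn(2)
    row_rngs = [np.random.default_rng(s) for s in rows_ss.spawn(config.n_trees)]
    key_rng = np.random.default_rng(key_ss)
    tree_keys = key_rng.integers(0, 2**63, size=config.n_trees, dtype=np.uint64)

    m_sub = max(2, int(round(config.subsample_fraction * n)))
    m_sub = min(m_sub, n)
    trees = []
    subsamples = []
    for t in range(config.n_trees):
        sub = np.sort(row_rngs[t].choice(n, size=m_sub, replace=False))
        tree = fit_tree(X[sub], y[sub], config, task, tree_key=int(tree_keys[t]))
        trees.append(tree)
        subsamples.append(sub.astype(np.intp))
    return ForestModel(
        trees=trees,
        subsample_indices=subsamples,
        config=config,
        task=task,
        n_features=p,
        seed=int(seed),
        feature_names=list(feature_names) if feature_names is not None else None,
        _train_shape=(n, p),
    )


def predict_proba(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Mean of per-tree leaf values: P(class 1) or the regression mean."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, rows have {X.shape[1]}"
        )
    out = np.zeros(X.shape[0])
    for tree in model.trees:
        out += tree.predict(X)
    return out / len(model.trees)


def predict(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Hard predictions: majority probability for classification (tie goes
    to class 0, the first class in canonical order), mean for regression."""
    prob = predict_proba(model, X)
    if model.task == "classification":
        return (prob > 0.5).astype(float)
    return prob


def _tree_metric(tree: Tree, X: np.ndarray, y: np.ndarray, task: str) -> float:
    pred = tree.predict(X)
    if task == "classification":
        return float(np.mean((pred > 0.5) == (y > 0.5)))
    resid = y - pred
    return -float(resid @ resid) / y.size


def permutation_importance(
    model: ForestModel,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_permutations: Optional[int] = None,
    eval_rows: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Permutation variable importance.

    importance(f) = mean over trees of (baseline metric - mean metric after
    permuting column f), each tree evaluated on its own out-of-subsample
    rows (or on ``eval_rows`` if given).  The metric is accuracy for
    classification and negative mean squared error for regression.  A
    feature untouched by a tree's splits contributes exactly 0 for it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError("feature count mismatch")
    n_perm = n_permutations or model.config.n_permutations
    n = X.shape[0]
    imp = np.zeros(model.n_features)
    rng_root = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    tree_rngs = [np.random.default_rng(s) for s in rng_root.spawn(len(model.trees))]

    for t, tree in enumerate(model.trees):
        if eval_rows is not None:
            rows = np.asarray(eval_rows, dtype=np.intp)
        else:
            mask = np.ones(n, dtype=bool)
            mask[model.subsample_indices[t]] = False
            rows = np.flatnonzero(mask)
        if rows.size == 0:
            continue
        used = tree.used_features()
        if used.size == 0:
            continue
        Xe = X[rows]
        ye = y[rows]
        base = _tree_metric(tree, Xe, ye, model.task)
        rng = tree_rngs[t]
        for f in used:
            degr = 0.0
            col = Xe[:, f].copy()
            for _ in range(n_perm):
                Xe[:, f] = col[rng.permutation(rows.size)]
                degr += base - _tree_metric(tree, Xe, ye, model.task)
            Xe[:, f] = col
            imp[f] += degr / n_perm
    return imp / len(model.trees)
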