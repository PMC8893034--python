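"""Gini-impurity classification tree (CART) with cost-complexity pruning.

A small, deterministic re-implementation of classification-tree analysis
as classical statistics packages run it: greedy binary splits maximising
the weighted Gini impurity decrease, candidate thresholds at midpoints of
consecutive sorted unique feature values, a hard depth cap and a minimum
terminal-node size, and automated minimal cost-complexity pruning with the
penalty chosen by seeded k-fold cross-validation under the 1-SE rule.

Conventions (fixed for determinism):

* the left branch takes rows with feature value strictly below the
  threshold; rows exactly at the threshold go right;
* ties in impurity decrease break toward the lowest feature index in the
  declared column order, then the smallest threshold;
* leaf predictions are the majority class, ties broken by class order.

No surrogate splits: a missing feature value at prediction time is an
error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "TreeConfig",
    "ClassificationReport",
    "gini",
    "grow_tree",
    "prune",
    "predict",
    "classification_report",
]

_EPS = 1e-12


def gini(class_counts: Sequence[float] | Mapping[str, float]) -> float:
    """Gini impurity ``1 - sum((c_i / n)^2)`` of a node's class counts."""
    counts = np.asarray(
        list(class_counts.values()) if isinstance(class_counts, Mapping) else class_counts,
        dtype=float,
    )
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("gini undefined for all-zero counts")
    p = counts / total
    return float(1.0 - (p**2).sum())


@dataclass
class TreeConfig:
    """Hyperparameters of the classification tree.

    Defaults mirror a small-cohort clinical configuration: depth at most
    2, at least 3 patients per terminal node, Gini impurity, and automated
    cost-complexity pruning with 10-fold cross-validation.
    """

    max_depth: int = 2
    min_terminal_size: int = 3
    impurity: str = "gini"
    pruning: str = "cost_complexity_cv"  # or "none"
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_terminal_size < 1:
            raise ValueError("min_terminal_size must be >= 1")
        if self.impurity != "gini":
            raise ValueError(f"unsupported impurity {self.impurity!r}")
        if self.pruning not in ("none", "cost_complexity_cv"):
            raise ValueError(f"unsupported pruning {self.pruning!r}")


@dataclass
class TreeNode:
    """One node of a binary classification tree."""

    node_id: int
    depth: int
    class_counts: dict[str, int]
    prediction: str
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()  # type: ignore[union-attr]
            yield from self.right.leaves()  # type: ignore[union-attr]

    def internal_nodes(self) -> Iterator["TreeNode"]:
        if not self.is_leaf:
            yield self
            yield from self.left.internal_nodes()  # type: ignore[union-attr]
            yield from self.right.internal_nodes()  # type: ignore[union-attr]

    @property
    def tree_depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.tree_depth, self.right.tree_depth)  # type: ignore[union-attr]

    @property
    def n_misclassified(self) -> int:
        return self.n - self.class_counts.get(self.prediction, 0)

    def subtree_misclassified(self) -> int:
        return sum(leaf.n_misclassified for leaf in self.leaves())

    def collapse(self) -> None:
        """Turn this node into a leaf (its class counts are unchanged)."""
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.node_id,
            self.depth,
            dict(self.class_counts),
            self.prediction,
            self.feature,
            self.threshold,
            self.left.copy() if self.left else None,
            self.right.copy() if self.right else None,
        )

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "class_counts": self.class_counts,
            "prediction": self.prediction,
        }
        if not self.is_leaf:
            d["feature"] = self.feature
            d["threshold"] = self.threshold
            d["left"] = self.left.to_dict()  # type: ignore[union-attr]
            d["right"] = self.right.to_dict()  # type: ignore[union-attr]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            d["node_id"], d["depth"], dict(d["class_counts"]), d["prediction"],
            d.get("feature"), d.get("threshold"),
        )
        if "left" in d:
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node

    def render(self, indent: str = "") -> str:
        """Indented text rendering: split rule per branch, counts per node."""
        counts = ", ".join(f"{k}: {v}" for k, v in self.class_counts.items())
        if self.is_leaf:
            return f"{indent}predict {self.prediction}  [{counts}]\n"
        out = f"{indent}node {self.node_id}  [{counts}]\n"
        out += f"{indent}if {self.feature} < {self.threshold:g}:\n"
        out += self.left.render(indent + "  ")  # type: ignore[union-attr]
        out += f"{indent}else ({self.feature} >= {self.threshold:g}):\n"
        out += self.right.render(indent + "  ")  # type: ignore[union-attr]
        return out


def _counts(y: np.ndarray, classes: Sequence[str]) -> dict[str, int]:
    return {c: int((y == c).sum()) for c in classes}


def _majority(counts: dict[str, int]) -> str:
    # ties break toward the earlier class in declared order
    best = max(counts.values())
    for c, v in counts.items():
        if v == best:
            return c
    raise ValueError("empty node")


def _as_frame(features) -> pd.DataFrame:
    X = pd.DataFrame(features)
    bad = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if bad:
        raise ValueError(
            f"non-numeric feature columns {bad}; encode categoricals as 0/1 indicators"
        )
    if X.isna().any().any():
        raise ValueError("missing feature values are not supported (no surrogate splits)")
    return X


def grow_tree(
    features,
    labels: Sequence[str],
    config: TreeConfig | None = None,
) -> TreeNode:
    """Grow a classification tree by greedy Gini splitting.

    ``features`` is a DataFrame (or convertible) of numeric columns;
    ``labels`` the class per row. Single-class data yields a single leaf.
    The result is fully determined by the input and the config.
    """
    config = config or TreeConfig()
    X = _as_frame(features)
    y = np.asarray(labels, dtype=object)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} feature rows but {len(y)} labels")
    if len(y) == 0:
        raise ValueError("empty training data")
    classes = list(dict.fromkeys(y))  # first-appearance order, deterministic
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)

    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = _counts(y[idx], classes)
        node = TreeNode(counter[0], depth, counts, _majority(counts))
        counter[0] += 1
        node_gini = gini(counts)
        if depth >= config.max_depth or node_gini <= 0 or len(idx) < 2 * config.min_terminal_size:
            return node

        best = None  # (decrease, col_pos, threshold, left_idx, right_idx)
        for ci, _col in enumerate(cols):
            v = Xv[idx, ci]
            uniq = np.unique(v)
            if len(uniq) < 2:
                continue
            thresholds = (uniq[:-1] + uniq[1:]) / 2.0
            for thr in thresholds:
                go_left = v < thr
                n_left = int(go_left.sum())
                n_right = len(idx) - n_left
                if n_left < config.min_terminal_size or n_right < config.min_terminal_size:
                    continue
                yl, yr = y[idx[go_left]], y[idx[~go_left]]
                g = (
                    n_left * gini(_counts(yl, classes))
                    + n_right * gini(_counts(yr, classes))
                ) / len(idx)
                decrease = node_gini - g
                if decrease <= _EPS:
                    continue
                if best is None or decrease > best[0] + _EPS:
                    best = (decrease, ci, float(thr), idx[go_left], idx[~go_left])
                # equal decrease: keep the earlier column / smaller threshold
        if best is None:
            return node
        _, ci, thr, left_idx, right_idx = best
        node.feature = cols[ci]
        node.threshold = thr
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    return build(np.arange(len(y)), 0)


def predict(tree: TreeNode, rows) -> np.ndarray:
    """Route each row through the tree; return the leaf majority classes.

    A row exactly at a threshold goes to the right (>=) branch. Missing
    features or NaN values are errors.
    """
    X = pd.DataFrame(rows)
    out = []
    for _, row in X.iterrows():
        node = tree
        while not node.is_leaf:
            if node.feature not in row.index:
                raise KeyError(f"row lacks feature {node.feature!r}")
            v = row[node.feature]
            if pd.isna(v):
                raise ValueError(f"missing value for feature {node.feature!r}")
            node = node.left if float(v) < node.threshold else node.right  # type: ignore[operator]
        out.append(node.prediction)
    return np.asarray(out, dtype=object)


# --- cost-complexity pruning -------------------------------------------


def _weakest_link(tree: TreeNode, n_total: int) -> tuple[float, TreeNode] | None:
    """Internal node with the smallest cost-complexity link strength g(t).

    ``g(t) = (R(t) - R(T_t)) / (|leaves(T_t)| - 1)`` with R measured as
    misclassification rate over the full training set. Ties break toward
    the larger node id (deeper/later node) so inner splits collapse first.
    """
    best: tuple[float, TreeNode] | None = None
    for node in tree.internal_nodes():
        n_leaves = sum(1 for _ in node.leaves())
        g = (node.n_misclassified - node.subtree_misclassified()) / (
            n_total * (n_leaves - 1)
        )
        if best is None or g < best[0] - _EPS or (
            abs(g - best[0]) <= _EPS and node.node_id > best[1].node_id
        ):
            best = (g, node)
    return best


def _prune_at_alpha(tree: TreeNode, alpha: float, n_total: int) -> TreeNode:
    """Collapse weakest links while their link strength is <= alpha."""
    t = tree.copy()
    while True:
        wl = _weakest_link(t, n_total)
        if wl is None or wl[0] > alpha + _EPS:
            return t
        wl[1].collapse()


def _pruning_path(tree: TreeNode, n_total: int) -> list[float]:
    """Increasing sequence of critical alphas of the minimal pruning path."""
    alphas = [0.0]
    t = tree.copy()
    while True:
        wl = _weakest_link(t, n_total)
        if wl is None:
            return alphas
        g, node = wl
        if g > alphas[-1] + _EPS:
            alphas.append(g)
        node.collapse()


def prune(
    tree: TreeNode,
    features,
    labels: Sequence[str],
    config: TreeConfig | None = None,
) -> TreeNode:
    """Minimal cost-complexity pruning with cross-validated penalty.

    Candidate penalties are the critical alphas of the full tree's pruning
    path (geometric interior points between consecutive alphas, as is
    conventional). For each seeded fold, a tree grown on the training
    part is pruned at every candidate and scored by held-out
    misclassification; the chosen alpha is the largest whose mean risk is
    within one standard error of the minimum (1-SE rule). Pruning never
    deepens the tree. With ``config.pruning == "none"`` the tree is
    returned unchanged (a copy).
    """
    config = config or TreeConfig()
    if config.pruning == "none" or tree.is_leaf:
        return tree.copy()
    X = _as_frame(features)
    y = np.asarray(labels, dtype=object)
    n = len(y)

    path = _pruning_path(tree, n)
    if len(path) == 1:
        return tree.copy()
    # interior candidates between consecutive critical alphas, plus the
    # endpoints: alpha just above the last critical value collapses to root
    candidates = [0.0]
    for a0, a1 in zip(path[:-1], path[1:]):
        candidates.append(math.sqrt(max(a0, _EPS) * a1) if a0 > 0 else a1 / 2.0)
    candidates.append(path[-1] * 1.001)

    folds = max(2, min(config.cv_folds, n))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for i, row in enumerate(order):
        fold_of[row] = i % folds

    risks = np.zeros((folds, len(candidates)))
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if len(set(y[train])) < 2:
            # degenerate fold: constant prediction, same risk at all alphas
            pred = pd.Series(y[train]).mode().iloc[0] if train.any() else y[0]
            risks[f, :] = (y[test] != pred).mean()
            continue
        sub = grow_tree(X[train], y[train], config)
        for ai, alpha in enumerate(candidates):
            pruned = _prune_at_alpha(sub, alpha, int(train.sum()))
            risks[f, ai] = (predict(pruned, X[test]) != y[test]).mean()

    mean_risk = risks.mean(axis=0)
    se_risk = risks.std(axis=0, ddof=1) / math.sqrt(folds)
    i_min = int(np.argmin(mean_risk))
    cutoff = mean_risk[i_min] + se_risk[i_min]
    chosen = max(
        (candidates[i] for i in range(len(candidates)) if mean_risk[i] <= cutoff + _EPS),
        default=candidates[i_min],
    )
    return _prune_at_alpha(tree, chosen, n)


# --- evaluation ---------------------------------------------------------


@dataclass
class ClassificationReport:
    """Confusion matrix and one-vs-rest diagnostic metrics (percent).

    ``confusion`` has true classes as rows and predicted as columns.
    Per-class metrics are NaN where their denominator is zero.
    """

    confusion: pd.DataFrame
    accuracy_percent: float
    per_class: pd.DataFrame  # rows: classes; cols: ppv, npv, sensitivity, specificity
    n: int = field(default=0)

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy_percent:.1f}% (n={self.n})\n"
            f"{self.confusion}\n{self.per_class.round(1)}"
        )


def classification_report(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ClassificationReport:
    """Accuracy, confusion matrix, and per-class PPV/NPV/sensitivity/specificity.

    All metrics are percentages. PPV (positive predictive value) is the
    share of predictions of a class that are correct; NPV the share of
    non-predictions that are correctly not that class; sensitivity the
    share of the class's true members predicted as it; specificity the
    share of non-members not predicted as it.
    """
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    if len(yt) == 0:
        raise ValueError("empty input")
    if len(yt) != len(yp):
        raise ValueError(f"{len(yt)} true labels but {len(yp)} predictions")
    classes = list(class_order) if class_order is not None else sorted(
        set(yt) | set(yp), key=str
    )
    extra = (set(yt) | set(yp)) - set(classes)
    if extra:
        raise ValueError(f"labels {sorted(extra, key=str)} missing from class_order")

    n = len(yt)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(yt, yp):
        conf.loc[t, p] += 1
    accuracy = 100.0 * np.trace(conf.to_numpy()) / n

    rows = {}
    for c in classes:
        tp = int(conf.loc[c, c])
        fp = int(conf[c].sum()) - tp
        fn = int(conf.loc[c].sum()) - tp
        tn = n - tp - fp - fn
        rows[c] = {
            "ppv": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
            "npv": 100.0 * tn / (tn + fn) if tn + fn else float("nan"),
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        }
    per_class = pd.DataFrame(rows).T[["ppv", "npv", "sensitivity", "specificity"]]
    return ClassificationReport(conf, float(accuracy), per_class, n)
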