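"""Classification trees for post-hoc latent-class characterization.

Greedy CART with Gini impurity, complexity-parameter pre-pruning (a split
must reduce overall impurity by at least cp times the root impurity),
10-fold cross-validated cp tuning, and impurity-decrease variable
importance.  Complete-case inputs only; no surrogate splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pacctraj.errors import SpecificationError
from pacctraj.evaluate import stratified_folds

DEFAULT_CP_GRID = (0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05)


def gini(counts) -> float:
    """Gini impurity ``1 - sum p^2`` of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


@dataclass
class TreeNode:
    class_counts: np.ndarray
    impurity: float
    predicted_class: int
    split_variable: str | None = None
    split_threshold: float | None = None  # left iff value < threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self):
        d = {
            "class_counts": self.class_counts.tolist(),
            "impurity": self.impurity,
            "predicted_class": int(self.predicted_class),
        }
        if not self.is_leaf:
            d["split_variable"] = self.split_variable
            d["split_threshold"] = self.split_threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list
    classes: list
    complexity_parameter: float
    min_split: int
    min_bucket: int
    n_total: int
    cv_accuracy: float | None = None
    cv_balanced_accuracy: tuple | None = None  # (mean, se)
    _importance_raw: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X), dtype=int)
        cols = {name: X[name].to_numpy(dtype=float) for name in self.feature_names}
        for i in range(len(X)):
            node = self.root
            while not node.is_leaf:
                v = cols[node.split_variable][i]
                node = node.left if v < node.split_threshold else node.right
            out[i] = self.classes[node.predicted_class]
        return out

    def variable_importance(self) -> pd.Series:
        """Impurity-decrease importance normalized to percentages (sum 100)."""
        if not self._importance_raw:
            return pd.Series(dtype=float)
        s = pd.Series(self._importance_raw, dtype=float)
        return (100.0 * s / s.sum()).sort_values(ascending=False)

    def n_leaves(self) -> int:
        def count(node):
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def to_text(self) -> str:
        lines = []

        def walk(node, depth, prefix):
            counts = "/".join(str(int(c)) for c in node.class_counts)
            if node.is_leaf:
                lines.append(
                    f"{'  ' * depth}{prefix}leaf: class {self.classes[node.predicted_class]}"
                    f" [{counts}]"
                )
            else:
                lines.append(
                    f"{'  ' * depth}{prefix}{node.split_variable} < "
                    f"{node.split_threshold:.4g} [{counts}]"
                )
                walk(node.left, depth + 1, "yes: ")
                walk(node.right, depth + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "root": self.root.to_dict(),
                    "feature_names": self.feature_names,
                    "classes": [int(c) for c in self.classes],
                    "complexity_parameter": self.complexity_parameter,
                    "min_split": self.min_split,
                    "min_bucket": self.min_bucket,
                },
                fh,
                indent=2,
            )


def _best_split(X, y, G, feature_names, min_bucket):
    """Best (variable, threshold, impurity decrease, left mask) at a node.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties in impurity decrease break by feature order, then lower threshold.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=G)
    parent_imp = gini(parent_counts)
    best = None  # (gain, feat_idx, threshold)
    for j, name in enumerate(feature_names):
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        onehot = np.zeros((n, G))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)  # counts in left child after i+1 items
        boundary = np.flatnonzero(xs[1:] != xs[:-1])  # split after index i
        for i in boundary:
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_bucket or n_right < min_bucket:
                continue
            left_counts = cum[i]
            right_counts = parent_counts - left_counts
            child_imp = (
                n_left * gini(left_counts) + n_right * gini(right_counts)
            ) / n
            gain = parent_imp - child_imp
            thr = 0.5 * (xs[i] + xs[i + 1])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, thr)
    return best


def grow_tree(
    features: pd.DataFrame,
    labels,
    cp: float = 0.01,
    min_split: int = 20,
    min_bucket: int = 7,
) -> TreeModel:
    """Grow a CART by recursive Gini splitting with cp pre-pruning.

    A split is kept only when its overall impurity decrease — the node's
    weighted impurity drop, ``(n_node / n_total) * (imp - imp_children)`` —
    is at least ``cp`` times the root impurity.
    """
    feature_names = list(features.columns)
    X = features.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise SpecificationError("features must be complete (no missing values)")
    classes = sorted(set(np.asarray(labels).tolist()))
    y = np.searchsorted(classes, np.asarray(labels))
    G = len(classes)
    n_total = len(y)
    root_counts = np.bincount(y, minlength=G)
    root_imp = gini(root_counts)
    importance = {}

    def build(idx):
        yb = y[idx]
        counts = np.bincount(yb, minlength=G)
        node = TreeNode(
            class_counts=counts,
            impurity=gini(counts),
            predicted_class=int(counts.argmax()),
        )
        if len(idx) < min_split or node.impurity == 0.0 or root_imp == 0.0:
            return node
        best = _best_split(X[idx], yb, G, feature_names, min_bucket)
        if best is None:
            return node
        gain, j, thr = best
        overall_decrease = (len(idx) / n_total) * gain
        if overall_decrease < cp * root_imp:
            return node
        name = feature_names[j]
        importance[name] = importance.get(name, 0.0) + overall_decrease
        mask = X[idx, j] < thr
        node.split_variable = name
        node.split_threshold = float(thr)
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(np.arange(n_total))
    return TreeModel(
        root=root,
        feature_names=feature_names,
        classes=classes,
        complexity_parameter=cp,
        min_split=min_split,
        min_bucket=min_bucket,
        n_total=n_total,
        _importance_raw=importance,
    )


def tune_tree(
    features: pd.DataFrame,
    labels,
    cp_grid=DEFAULT_CP_GRID,
    K: int = 10,
    seed: int = 0,
    min_split: int = 20,
    min_bucket: int = 7,
):
    """cp tuning by class-stratified K-fold cross-validation.

    Best cp maximizes mean CV accuracy (ties break toward larger cp, the
    simpler tree); the final tree is refit on all data at the best cp.
    Returns ``(best_cp, TreeModel, cv_table)``; the model carries the CV
    accuracy and balanced accuracy (mean, SE over folds) at the best cp.
    """
    if not cp_grid:
        raise SpecificationError("cp grid must be non-empty")
    labels = np.asarray(labels)
    sids = {i: labels[i] for i in range(len(labels))}
    folds = stratified_folds(sids, K=K, seed=seed)
    classes = sorted(set(labels.tolist()))

    rows = []
    for cp in cp_grid:
        accs, baccs = [], []
        for k in range(K):
            test_idx = np.array(folds.subjects_in_fold(k))
            if len(test_idx) == 0:
                continue
            train_mask = np.ones(len(labels), dtype=bool)
            train_mask[test_idx] = False
            model = grow_tree(
                features[train_mask], labels[train_mask], cp, min_split, min_bucket
            )
            pred = model.predict(features.iloc[test_idx])
            t = labels[test_idx]
            accs.append(float((pred == t).mean()))
            recalls = [
                float(((t == c) & (pred == c)).sum() / (t == c).sum())
                for c in classes
                if (t == c).any()
            ]
            baccs.append(float(np.mean(recalls)))
        accs, baccs = np.asarray(accs), np.asarray(baccs)
        rows.append(
            {
                "cp": cp,
                "cv_accuracy": accs.mean(),
                "cv_balanced_accuracy": baccs.mean(),
                "cv_balanced_accuracy_se": baccs.std(ddof=1) / np.sqrt(len(baccs)),
            }
        )
    table = pd.DataFrame(rows)
    best_acc = table["cv_accuracy"].max()
    best_cp = float(
        table[table["cv_accuracy"] >= best_acc - 1e-12]["cp"].max()
    )
    model = grow_tree(features, labels, best_cp, min_split, min_bucket)
    at_best = table[table["cp"] == best_cp].iloc[0]
    model.cv_accuracy = float(at_best["cv_accuracy"])
    model.cv_balanced_accuracy = (
        float(at_best["cv_balanced_accuracy"]),
        float(at_best["cv_balanced_accuracy_se"]),
    )
    return best_cp, model, table


def variable_importance(model: TreeModel) -> pd.Series:
    """Functional alias for :meth:`TreeModel.variable_importance`."""
    return model.variable_importance()
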