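"""Decision-tree ensemble selection over binary STR-caller flags.

The classifier is a from-scratch CART binary decision tree over binary
features (one per STR caller), split by Gini impurity decrease.  Around it
sit the model-selection pieces used to pick the best combination of callers:
a stratified 80/20 train-test split, repeated stratified k-fold
cross-validation (default 5 x 10-fold = 50 train-validation splits),
exhaustive feature-subset selection by mean validation ROC AUC, and a grid
search over tree hyper-parameters.  Because the tree predicts hard labels,
ROC/PR curves are drawn from the full-mutation fraction at the leaf each
row lands in.

Everything here is deterministic given the input row order, the supplied
tool order, and one explicit seed: split ties are broken toward the highest
impurity decrease and then the lowest feature index; leaf-prediction ties go
to the full-mutation class (the screening-conservative choice); selection
ties prefer smaller subsets, then lexicographic order in the supplied tool
list; grid ties prefer the simplest model (smallest ``max_depth``, then
largest ``min_samples_leaf``).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .harmonize import LabeledMatrix, LABEL_FM, LABEL_NON_FM

__all__ = [
    "Hyperparameters",
    "CVScheme",
    "TreeNode",
    "DecisionTree",
    "EvaluationReport",
    "gini_impurity",
    "fit_tree",
    "stratified_split",
    "repeated_stratified_kfold",
    "roc_auc",
    "roc_curve",
    "pr_curve",
    "exhaustive_feature_selection",
    "grid_search",
    "default_grid",
    "evaluate",
    "feature_importances",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class Hyperparameters:
    """CART stopping/regularisation parameters."""

    max_depth: int = 6
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    min_impurity_decrease: float = 0.0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if min(self.min_samples_split, self.min_samples_leaf) < 1:
            raise ValueError("min sample counts must be >= 1")
        if self.min_impurity_decrease < 0:
            raise ValueError("min_impurity_decrease must be >= 0")


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold scheme (default 5 x 10 = 50 splits)."""

    k: int = 10
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity ``1 - sum(p_c^2)`` of a node's class counts.

    For two classes the value lies in [0, 0.5], with 0.5 at perfect balance
    and 0 at purity.
    """
    total = sum(class_counts)
    if total == 0:
        raise ValueError("empty node has no impurity")
    if min(class_counts) < 0:
        raise ValueError("negative class count")
    return 1.0 - sum((c / total) ** 2 for c in class_counts)


@dataclass
class TreeNode:
    """One CART node.

    ``value`` is ``(count full_mutation, count non_full_mutation)``; for
    internal nodes ``feature`` is the tool column index and the left/right
    children receive the rows with flag 0/1 respectively.
    """

    node_id: int
    gini: float
    samples: int
    value: tuple[int, int]
    feature: Optional[int] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def class_fraction(self) -> float:
        """Fraction of full-mutation rows at this node (the ROC score)."""
        return self.value[0] / self.samples

    @property
    def prediction(self) -> int:
        """Majority class (1 = full-mutation); ties go to full-mutation."""
        return 1 if self.value[0] >= self.value[1] else 0

    def to_dict(self) -> dict:
        d = {"node_id": self.node_id, "gini": self.gini,
             "samples": self.samples, "value": list(self.value),
             "feature": self.feature}
        if not self.is_leaf:
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(d["node_id"], float(d["gini"]), int(d["samples"]),
                   (int(d["value"][0]), int(d["value"][1])),
                   d.get("feature"))
        if node.feature is not None:
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class DecisionTree:
    """A fitted (or hand-specified) CART over binary tool flags."""

    root: TreeNode
    feature_names: tuple[str, ...]
    hyperparameters: Optional[Hyperparameters] = None
    metadata: dict = field(default_factory=dict)

    def _leaf_for(self, row: np.ndarray) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            val = row[node.feature]
            if val not in (0, 1):
                raise ValueError(
                    f"missing or non-binary value {val!r} for feature "
                    f"{self.feature_names[node.feature]!r}")
            node = node.right if val == 1 else node.left
        return node

    def _as_array(self, rows) -> np.ndarray:
        if isinstance(rows, LabeledMatrix):
            rows = rows.data
        if isinstance(rows, pd.DataFrame):
            missing = [t for t in self.feature_names if t not in rows.columns]
            if missing:
                raise ValueError(f"rows lack tree features {missing}")
            rows = rows[list(self.feature_names)].to_numpy()
        arr = np.asarray(rows)
        if arr.ndim != 2 or arr.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected shape (n, {len(self.feature_names)}), "
                f"got {arr.shape}")
        return arr

    def predict(self, rows) -> np.ndarray:
        """Hard labels (1 = full-mutation) for an array/DataFrame of flags."""
        arr = self._as_array(rows)
        return np.array([self._leaf_for(r).prediction for r in arr], dtype=int)

    def predict_score(self, rows) -> np.ndarray:
        """Leaf full-mutation fractions, used as ROC/PR scores."""
        arr = self._as_array(rows)
        return np.array([self._leaf_for(r).class_fraction for r in arr])

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.right, node.left])
        return sorted(out, key=lambda n: n.node_id)


def _grow(X: np.ndarray, y: np.ndarray, idx: np.ndarray, depth: int,
          hp: Hyperparameters, counter: itertools.count) -> TreeNode:
    n_fm = int(y[idx].sum())
    value = (n_fm, len(idx) - n_fm)
    node = TreeNode(next(counter), gini_impurity(value), len(idx), value)
    if (value[0] == 0 or value[1] == 0 or depth >= hp.max_depth
            or len(idx) < hp.min_samples_split):
        return node
    best_feature, best_dec, best_parts = None, 0.0, None
    for f in range(X.shape[1]):
        mask = X[idx, f] == 1
        right, left = idx[mask], idx[~mask]
        if (len(left) < hp.min_samples_leaf
                or len(right) < hp.min_samples_leaf):
            continue
        dec = node.gini
        for part in (left, right):
            n_fm_p = int(y[part].sum())
            dec -= (len(part) / len(idx)) * gini_impurity(
                (n_fm_p, len(part) - n_fm_p))
        # strictly-greater comparison keeps the lowest feature index on ties
        if dec > best_dec + _TIE_TOL:
            best_feature, best_dec, best_parts = f, dec, (left, right)
    if (best_feature is None or best_dec <= _TIE_TOL
            or best_dec < hp.min_impurity_decrease - _TIE_TOL):
        return node
    node.feature = best_feature
    left, right = best_parts
    node.left = _grow(X, y, left, depth + 1, hp, counter)
    node.right = _grow(X, y, right, depth + 1, hp, counter)
    return node


def fit_tree(matrix: LabeledMatrix | tuple[np.ndarray, np.ndarray],
             hp: Hyperparameters | None = None,
             feature_names: Sequence[str] | None = None) -> DecisionTree:
    """Fit a greedy CART on a labeled binary matrix.

    At each node the binary feature with the largest weighted Gini impurity
    decrease splits the rows (flag 0 left, flag 1 right); growth stops on
    purity, depth, minimum sample counts, or non-positive decrease.  The
    result is deterministic given the input row order.
    """
    hp = hp or Hyperparameters()
    if isinstance(matrix, LabeledMatrix):
        X, y = matrix.X, matrix.y
        feature_names = matrix.tools
    else:
        X, y = (np.asarray(a) for a in matrix)
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    if len(X) == 0 or X.shape[1] == 0:
        raise ValueError("cannot fit a tree on an empty matrix")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("features must be binary flags")
    root = _grow(X, y, np.arange(len(X)), 0, hp, itertools.count())
    return DecisionTree(root, tuple(feature_names), hp)


# ---------------------------------------------------------------------------
# Stratified splitting and cross-validation
# ---------------------------------------------------------------------------

def _class_quotas(class_sizes: Sequence[int], n_take: int,
                  fraction: float) -> list[int]:
    """Largest-remainder allocation of *n_take* rows across classes."""
    exact = [fraction * n for n in class_sizes]
    quotas = [min(math.floor(e), n) for e, n in zip(exact, class_sizes)]
    remainder = n_take - sum(quotas)
    order = sorted(range(len(class_sizes)),
                   key=lambda i: (-(exact[i] - quotas[i]), -class_sizes[i], i))
    for i in itertools.cycle(order):
        if remainder <= 0:
            break
        if quotas[i] < class_sizes[i]:
            quotas[i] += 1
            remainder -= 1
    return quotas


def stratified_split(matrix: LabeledMatrix, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Class-stratified train/test partition, reproducible by seed.

    The test partition receives ``ceil(test_fraction * n)`` rows (e.g.
    1176 rows -> 940 train / 236 test), allocated across classes by largest
    remainder so per-class proportions are preserved to rounding.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = matrix.y
    n_test = math.ceil(test_fraction * len(y))
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(y == c) for c in (1, 0)]
    quotas = _class_quotas([len(ci) for ci in class_idx], n_test,
                           test_fraction)
    test_pos: list[int] = []
    for ci, q in zip(class_idx, quotas):
        perm = rng.permutation(ci)
        test_pos.extend(perm[:q].tolist())
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_pos] = True
    return (matrix.subset_rows(np.flatnonzero(~test_mask)),
            matrix.subset_rows(np.flatnonzero(test_mask)))


def repeated_stratified_kfold(matrix: LabeledMatrix,
                              scheme: CVScheme = CVScheme(),
                              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-position (train, validation) pairs for k x repeats CV splits.

    Within each repeat the validation folds partition the rows, and each
    fold preserves the class proportions up to rounding.
    """
    y = matrix.y
    splits = []
    for rep in range(scheme.repeats):
        rng = np.random.default_rng([scheme.seed, rep])
        folds: list[list[int]] = [[] for _ in range(scheme.k)]
        for c in (1, 0):
            perm = rng.permutation(np.flatnonzero(y == c))
            for i, pos in enumerate(perm):
                folds[i % scheme.k].append(int(pos))
        for fold in folds:
            val = np.array(sorted(fold), dtype=int)
            mask = np.ones(len(y), dtype=bool)
            mask[val] = False
            splits.append((np.flatnonzero(mask), val))
    return splits


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney concordance identity.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def roc_curve(labels: Sequence[int], scores: Sequence[float],
              ) -> list[tuple[float, float]]:
    """(FPR, TPR) points over all distinct score thresholds, plus (0, 0)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), len(y) - int(y.sum())
    points = [(0.0, 0.0)]
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        points.append((fp / n_neg if n_neg else 0.0,
                       tp / n_pos if n_pos else 0.0))
    return points


def pr_curve(labels: Sequence[int], scores: Sequence[float],
             ) -> list[tuple[float, float]]:
    """(recall, precision) points over all distinct score thresholds."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    points = []
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        precision = tp / (tp + fp) if tp + fp else 1.0
        points.append((tp / n_pos if n_pos else 0.0, precision))
    return points


# ---------------------------------------------------------------------------
# Feature-subset selection and hyper-parameter search
# ---------------------------------------------------------------------------

def _cv_mean_auc(matrix: LabeledMatrix, feature_idx: Sequence[int],
                 splits: Sequence[tuple[np.ndarray, np.ndarray]],
                 hp: Hyperparameters, use_scores: bool = True) -> float:
    X, y = matrix.X[:, list(feature_idx)], matrix.y
    names = tuple(matrix.tools[i] for i in feature_idx)
    aucs = []
    for train, val in splits:
        if len(set(y[train])) < 2 or len(set(y[val])) < 2:
            logger.warning(
                "single-class CV fold; contributing AUC 0.5 for features %s",
                names)
            aucs.append(0.5)
            continue
        tree = fit_tree((X[train], y[train]), hp, names)
        scores = (tree.predict_score(X[val]) if use_scores
                  else tree.predict(X[val]).astype(float))
        aucs.append(roc_auc(y[val], scores))
    return float(np.mean(aucs))


def exhaustive_feature_selection(matrix: LabeledMatrix,
                                 tools: Sequence[str] | None = None,
                                 scheme: CVScheme = CVScheme(),
                                 hp: Hyperparameters | None = None,
                                 use_scores: bool = True,
                                 ) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate every non-empty tool subset by mean CV ROC AUC.

    Returns the winning subset (ties resolved toward fewer tools, then
    lexicographic position in the supplied tool order) and the full
    per-subset table, sorted best-first.
    """
    tools = tuple(tools if tools is not None else matrix.tools)
    if not 1 <= len(tools) <= 12:
        raise ValueError("between 1 and 12 tools are supported")
    missing = [t for t in tools if t not in matrix.tools]
    if missing:
        raise ValueError(f"tools absent from matrix: {missing}")
    hp = hp or Hyperparameters()
    splits = repeated_stratified_kfold(matrix, scheme)
    tool_pos = {t: matrix.tools.index(t) for t in tools}
    rows = []
    best_key, best_subset = None, None
    for size in range(1, len(tools) + 1):
        for combo in itertools.combinations(range(len(tools)), size):
            subset = tuple(tools[i] for i in combo)
            mean_auc = _cv_mean_auc(
                matrix, [tool_pos[t] for t in subset], splits, hp, use_scores)
            rows.append({"subset": subset, "size": size,
                         "mean_auc": mean_auc})
            # tie key: maximise AUC, then minimise size, then tool order
            key = (-round(mean_auc / _TIE_TOL) * _TIE_TOL, size, combo)
            if best_key is None or key < best_key:
                best_key, best_subset = key, subset
    table = pd.DataFrame(rows).sort_values(
        ["mean_auc", "size"], ascending=[False, True], kind="stable",
    ).reset_index(drop=True)
    return best_subset, table


def default_grid() -> list[Hyperparameters]:
    """Default hyper-parameter grid for the binary-feature tree."""
    return [Hyperparameters(d, s, l, m)
            for d in range(1, 7)
            for s in (2, 5, 10)
            for l in (1, 5, 10)
            for m in (0.0, 1e-4)]


def grid_search(matrix: LabeledMatrix, subset: Sequence[str],
                grid: Sequence[Hyperparameters] | None = None,
                scheme: CVScheme = CVScheme(),
                use_scores: bool = True) -> Hyperparameters:
    """Pick the grid point with the best mean CV AUC on the tool subset.

    Ties go to the simplest model: smallest ``max_depth``, then largest
    ``min_samples_leaf``.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    splits = repeated_stratified_kfold(matrix, scheme)
    feature_idx = [matrix.tools.index(t) for t in subset]
    best_key, best_hp = None, None
    for hp in grid:
        mean_auc = _cv_mean_auc(matrix, feature_idx, splits, hp, use_scores)
        key = (-round(mean_auc / _TIE_TOL) * _TIE_TOL, hp.max_depth,
               -hp.min_samples_leaf)
        if best_key is None or key < best_key:
            best_key, best_hp = key, hp
    return best_hp


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion counts, per-class metrics, curves, and averages.

    ``per_class`` maps each class label to precision/recall/F1/support;
    ``macro`` is the unweighted and ``weighted`` the support-weighted mean
    across the two classes.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    auc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None
    pr_points: Optional[list[tuple[float, float]]] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_frame(self) -> pd.DataFrame:
        rows = {**self.per_class, "macro avg": self.macro,
                "weighted avg": self.weighted}
        df = pd.DataFrame(rows).T
        df["accuracy"] = self.accuracy
        return df


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def evaluate(labels: Sequence[int], predictions: Sequence[int],
             scores: Sequence[float] | None = None) -> EvaluationReport:
    """Classification report for binary full-mutation predictions.

    ``labels``/``predictions`` are 1 for full-mutation; ``scores`` (leaf
    fractions) additionally produce ROC/PR curves and the AUC.
    """
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    if y.shape != pred.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    per_class = {}
    for label, (tp_c, fp_c, fn_c, support) in {
            LABEL_FM: (tp, fp, fn, tp + fn),
            LABEL_NON_FM: (tn, fn, fp, tn + fp)}.items():
        p, r, f1 = _prf(tp_c, fp_c, fn_c)
        per_class[label] = {"precision": p, "recall": r, "f1": f1,
                            "support": support}
    n = len(y)
    accuracy = (tp + tn) / n if n else 0.0
    macro = {m: float(np.mean([per_class[c][m] for c in per_class]))
             for m in ("precision", "recall", "f1")}
    weighted = {m: (sum(per_class[c][m] * per_class[c]["support"]
                        for c in per_class) / n if n else 0.0)
                for m in ("precision", "recall", "f1")}
    auc = roc_pts = pr_pts = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        roc_pts = roc_curve(y, scores)
        pr_pts = pr_curve(y, scores)
        if 0 < y.sum() < len(y):
            auc = roc_auc(y, scores)
    return EvaluationReport(tp, fp, tn, fn, per_class, accuracy, macro,
                            weighted, auc, roc_pts, pr_pts)


def feature_importances(tree: DecisionTree) -> dict[str, float]:
    """Normalised Gini importance per tool.

    Each internal node contributes (node samples / total samples) times its
    impurity decrease to the feature it splits on; the result is normalised
    to sum to one (zero for unused features).
    """
    total = tree.root.samples
    raw = dict.fromkeys(tree.feature_names, 0.0)
    for node in tree.nodes():
        if node.is_leaf:
            continue
        dec = node.gini
        for child in (node.left, node.right):
            dec -= (child.samples / node.samples) * child.gini
        raw[tree.feature_names[node.feature]] += (node.samples / total) * dec
    norm = sum(raw.values())
    if norm > 0:
        raw = {k: v / norm for k, v in raw.items()}
    return raw


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

def save_model(tree: DecisionTree, path: str | Path) -> None:
    """Serialize a tree (nodes + tool order + metadata) to JSON."""
    doc = {
        "format": "strscreen-tree",
        "feature_names": list(tree.feature_names),
        "hyperparameters": (asdict(tree.hyperparameters)
                            if tree.hyperparameters else None),
        "metadata": tree.metadata,
        "root": tree.root.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> DecisionTree:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "strscreen-tree":
        raise ValueError(f"{path} is not a serialized strscreen tree")
    hp = (Hyperparameters(**doc["hyperparameters"])
          if doc.get("hyperparameters") else None)
    return DecisionTree(TreeNode.from_dict(doc["root"]),
                        tuple(doc["feature_names"]), hp,
                        doc.get("metadata", {}))
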