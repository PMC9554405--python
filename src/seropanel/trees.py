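"""Decision-tree biomarker panels with cross-validated confusion matrices.

CART-style binary trees with Gini impurity: candidate cutoffs are midpoints
between consecutive distinct values of each analyte, ``value < cutoff`` goes
left and ``value >= cutoff`` right, growth stops on depth, leaf size or zero
gain.  Panels are evaluated with stratified k-fold cross-validation pooled
into a confusion matrix; per-class "success" is recall.  Rules render in the
reporting style "analyte (< cutoff pg/ml -> class or branch)" with cutoffs
on the pg/ml scale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "PanelTree",
    "ConfusionMatrix",
    "CrossValidationResult",
    "grow_tree",
    "predict_tree",
    "kfold_evaluate",
    "extract_panel_rules",
    "parse_panel_rules",
]


@dataclass
class TreeNode:
    # internal nodes
    analyte: str | None = None
    cutoff: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    # leaves
    label: object | None = None
    distribution: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.analyte is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label, "distribution": dict(self.distribution)}
        return {
            "analyte": self.analyte,
            "cutoff": self.cutoff,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def _best_split(X: np.ndarray, y_idx: np.ndarray, n_classes: int, min_leaf: int):
    """Exhaustive Gini search: (feature, cutoff, gain) or None.

    Ties break on higher gain strictly, so the first (feature-order, then
    lowest-cutoff) optimum is kept — deterministic given the input.
    """
    n, p = X.shape
    parent_counts = np.bincount(y_idx, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y_idx[order]
        left = np.zeros(n_classes)
        right = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i + 1] == xs[i]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            gain = parent_gini - (n_left * _gini(left) + n_right * _gini(right)) / n
            if best is None or gain > best[2] + 1e-12:
                cutoff = 0.5 * (xs[i] + xs[i + 1])
                best = (j, cutoff, gain)
    if best is None or best[2] <= 1e-12:
        return None
    return best


class PanelTree:
    """A CART classifier over a small panel of analytes.

    Parameters mirror the growth limits: ``max_depth`` (default 4, panels in
    this setting are shallow) and ``min_leaf`` samples per leaf (default 3).
    """

    def __init__(self, max_depth: int = 4, min_leaf: int = 3):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.root_: TreeNode | None = None
        self.classes_: list = []
        self.analytes_: list[str] = []

    # -- fitting -------------------------------------------------------------
    def fit(self, values: pd.DataFrame, labels: pd.Series) -> "PanelTree":
        if len(values) == 0:
            raise ValueError("empty training set")
        labels = pd.Series(np.asarray(labels), index=values.index)
        self.classes_ = sorted(labels.unique())
        self.analytes_ = list(values.columns)
        self._prevalence = labels.value_counts()
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = labels.map(class_index).to_numpy()
        X = values.to_numpy(dtype=float)
        self.root_ = self._grow(X, y_idx, depth=0)
        return self

    def _leaf(self, y_idx: np.ndarray) -> TreeNode:
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        top = counts.max()
        tied = [self.classes_[i] for i in range(len(counts)) if counts[i] == top]
        if len(tied) > 1:
            # tie: prefer the class more prevalent in the full training set,
            # then label order
            tied.sort(key=lambda c: (-self._prevalence.get(c, 0), self.classes_.index(c)))
        return TreeNode(
            label=tied[0],
            distribution={self.classes_[i]: int(counts[i]) for i in range(len(counts))},
        )

    def _grow(self, X: np.ndarray, y_idx: np.ndarray, depth: int) -> TreeNode:
        if (
            depth >= self.max_depth
            or len(y_idx) < 2 * self.min_leaf
            or np.unique(y_idx).size == 1
        ):
            return self._leaf(y_idx)
        split = _best_split(X, y_idx, len(self.classes_), self.min_leaf)
        if split is None:
            return self._leaf(y_idx)
        j, cutoff, _ = split
        mask = X[:, j] < cutoff
        return TreeNode(
            analyte=self.analytes_[j],
            cutoff=cutoff,
            left=self._grow(X[mask], y_idx[mask], depth + 1),
            right=self._grow(X[~mask], y_idx[~mask], depth + 1),
        )

    # -- prediction ----------------------------------------------------------
    def predict_one(self, sample) -> tuple[object, list[tuple[str, float, str]]]:
        """Label plus the (analyte, cutoff, branch) path taken."""
        node = self.root_
        path = []
        while not node.is_leaf:
            value = sample[node.analyte]
            if pd.isna(value):
                raise ValueError(f"missing value for {node.analyte!r} on decision path")
            if value < node.cutoff:
                path.append((node.analyte, node.cutoff, "<"))
                node = node.left
            else:
                path.append((node.analyte, node.cutoff, ">="))
                node = node.right
        return node.label, path

    def predict(self, values: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.predict_one(row)[0] for _, row in values.iterrows()], index=values.index
        )


def grow_tree(values: pd.DataFrame, labels, max_depth: int = 4, min_leaf: int = 3) -> PanelTree:
    """Fit a CART panel tree (functional facade over :class:`PanelTree`)."""
    return PanelTree(max_depth=max_depth, min_leaf=min_leaf).fit(
        values, pd.Series(np.asarray(labels), index=values.index)
    )


def predict_tree(tree: PanelTree, sample) -> tuple[object, list]:
    """Route one sample; value exactly at a cutoff takes the >= branch."""
    return tree.predict_one(sample)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """True x predicted counts with per-class success (= recall, %)."""

    counts: pd.DataFrame  # rows true, columns predicted

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = pd.Series(np.asarray(y_true), name="true")
        y_pred = pd.Series(np.asarray(y_pred), name="predicted")
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        counts = (
            pd.crosstab(y_true, y_pred)
            .reindex(index=labels, columns=labels, fill_value=0)
        )
        return cls(counts=counts)

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    @property
    def per_class_success(self) -> pd.Series:
        """Recall per true class, in percent."""
        diag = pd.Series(np.diag(self.counts), index=self.counts.index)
        totals = self.counts.sum(axis=1)
        return 100.0 * diag / totals.replace(0, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.to_numpy().sum())


@dataclass
class CrossValidationResult:
    confusion: ConfusionMatrix          # pooled out-of-fold
    training_confusion: ConfusionMatrix
    k: int

    @property
    def per_class_success(self) -> pd.Series:
        return self.confusion.per_class_success

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    def summary(self) -> str:
        lines = [f"{self.k}-fold cross-validated panel performance"]
        for cls_, pct in self.per_class_success.items():
            lines.append(f"  {cls_}: {pct:.0f}% success (out-of-fold recall)")
        lines.append(f"  overall accuracy: {100 * self.accuracy:.1f}%")
        return "\n".join(lines)


def _stratified_folds(labels: pd.Series, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per sample, class-stratified, seeded shuffle."""
    folds = np.empty(len(labels), dtype=int)
    offset = 0
    for _, idx in labels.groupby(labels).groups.items():
        pos = labels.index.get_indexer(idx)
        rng.shuffle(pos)
        folds[pos] = (np.arange(len(pos)) + offset) % k
        offset += len(pos)  # stagger so fold sizes balance across classes
    return folds


def kfold_evaluate(
    values: pd.DataFrame,
    labels,
    k: int = 5,
    seed: int = 0,
    max_depth: int = 4,
    min_leaf: int = 3,
) -> CrossValidationResult:
    """Stratified k-fold CV of a panel tree, pooled out-of-fold confusion.

    When a class has fewer members than ``k``, k is lowered to the smallest
    class count (with a warning); k < 2 is a contract violation.
    """
    labels = pd.Series(np.asarray(labels), index=values.index)
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = labels.value_counts().min()
    if min_class < k:
        log.warning("smallest class has %d members; lowering k from %d", min_class, k)
        k = int(min_class)
        if k < 2:
            raise ValueError("smallest class has fewer than 2 members")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    class_order = sorted(labels.unique())

    y_pred = pd.Series(index=values.index, dtype=object)
    for fold in range(k):
        hold = folds == fold
        tree = grow_tree(values[~hold], labels[~hold], max_depth=max_depth, min_leaf=min_leaf)
        y_pred[hold] = tree.predict(values[hold])
    pooled = ConfusionMatrix.from_predictions(labels, y_pred, labels=class_order)

    full_tree = grow_tree(values, labels, max_depth=max_depth, min_leaf=min_leaf)
    training = ConfusionMatrix.from_predictions(
        labels, full_tree.predict(values), labels=class_order
    )
    return CrossValidationResult(confusion=pooled, training_confusion=training, k=k)


# ---------------------------------------------------------------------------
# Rule rendering
# ---------------------------------------------------------------------------

def extract_panel_rules(tree: PanelTree, transform=None) -> list[str]:
    """One human-readable rule per leaf, depth-first.

    Each rule concatenates the (analyte, cutoff, branch) conditions on the
    path and ends with the leaf class, e.g.
    ``"sCD47 <16.62 pg/ml; sCD27 >=2317.44 pg/ml -> CLL"``.  ``transform``
    maps cutoffs back to pg/ml when the tree was grown on transformed
    values (splits are monotone-invariant, so only the printed cutoff
    changes).
    """
    if tree.root_ is None:
        raise ValueError("tree not fitted")
    transform = transform or (lambda v: v)
    rules: list[str] = []

    def walk(node: TreeNode, conditions: list[str]) -> None:
        if node.is_leaf:
            lhs = "; ".join(conditions)
            rules.append(f"{lhs} -> {node.label}" if lhs else f"-> {node.label}")
            return
        cut = transform(node.cutoff)
        walk(node.left, conditions + [f"{node.analyte} <{cut:.10g} pg/ml"])
        walk(node.right, conditions + [f"{node.analyte} >={cut:.10g} pg/ml"])

    walk(tree.root_, [])
    return rules


_RULE_RE = re.compile(r"^\s*(?P<analyte>.+?)\s+(?P<op><|>=)(?P<cut>[-0-9.eE+]+)\s*pg/ml\s*$")


def parse_panel_rules(rules: list[str]) -> list[tuple[list[tuple[str, str, float]], str]]:
    """Parse rendered rules back into (conditions, class) structures."""
    parsed = []
    for rule in rules:
        lhs, _, label = rule.rpartition("->")
        conditions = []
        lhs = lhs.strip()
        if lhs:
            for part in lhs.split(";"):
                m = _RULE_RE.match(part)
                if not m:
                    raise ValueError(f"unparseable rule condition: {part!r}")
                conditions.append(
                    (m.group("analyte"), m.group("op"), float(m.group("cut")))
                )
        parsed.append((conditions, label.strip()))
    return parsed
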