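"""Scoring and error analysis for SF-LF extraction and reranking.

Pair-level precision/recall/F1, off-by-one categorization of candidate
LFs (n-best candidates tend to be exactly one word too long or too short,
usually at the left edge), charmatch conditional tables, per-rank correct
counts, and a small CART-style decision tree (Gini impurity, grown
greedily) for feature-importance analysis over binary features plus the
integer rank.  Every tree node reports the triple (best label, accuracy
of the best label, coverage), and child coverages sum to the parent's at
every level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_WS_RE = re.compile(r"\s+")

CORRECT = "correct"
OFF_BY_ONE = "off_by_one"
OTHERWISE = "otherwise"


def _norm(s: str, fold_case: bool = True) -> str:
    s = _WS_RE.sub(" ", s.strip())
    return s.lower() if fold_case else s


def _norm_tokens(s: str, fold_case: bool = True) -> tuple[str, ...]:
    return tuple(_norm(s, fold_case).split(" "))


@dataclass
class EvalReport:
    """Pair-level evaluation summary."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    categories: dict[str, int] = field(default_factory=dict)
    rank_histogram: dict[int, int] = field(default_factory=dict)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def score_pairs(predicted: Sequence, gold: Sequence, fold_case: bool = True) -> EvalReport:
    """Precision/recall/F1 of predicted (doc_id, sf, lf) triples against gold.

    A prediction matches a gold pair iff doc_id and sf match exactly and
    the LFs match under whitespace-collapsing, case-insensitive
    comparison.  Duplicate triples collapse to one (with a warning).
    """

    def key(p) -> tuple[str, str, str]:
        return (p.doc_id, p.sf, _norm(p.lf, fold_case))

    pred_keys = set()
    for p in predicted:
        k = key(p)
        if k in pred_keys:
            logger.warning("duplicate predicted pair %s collapsed", k)
        pred_keys.add(k)
    gold_keys = {key(g) for g in gold}

    tp = len(pred_keys & gold_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys)
    p, r, f = _prf(tp, fp, fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f)


@dataclass(frozen=True)
class Categorization:
    category: str  # correct | off_by_one | otherwise
    edge: str  # left | right | none
    delta: int  # +1 candidate one word too many, -1 one too few, 0 otherwise


def categorize(candidate_lf: str, gold_lf: str, fold_case: bool = True) -> Categorization:
    """Classify a candidate LF against gold: correct, off-by-one, or otherwise.

    Off-by-one means the token sequences differ by exactly one token added
    or removed at either end; the edge is recorded.
    """
    if not candidate_lf or not gold_lf:
        raise ValueError("candidate_lf and gold_lf must be non-empty")
    cand = _norm_tokens(candidate_lf, fold_case)
    gold = _norm_tokens(gold_lf, fold_case)
    if cand == gold:
        return Categorization(CORRECT, "none", 0)
    longer, shorter, delta = (cand, gold, +1) if len(cand) == len(gold) + 1 else (gold, cand, -1)
    if len(longer) == len(shorter) + 1:
        if longer[1:] == shorter:
            return Categorization(OFF_BY_ONE, "left", delta)
        if longer[:-1] == shorter:
            return Categorization(OFF_BY_ONE, "right", delta)
    return Categorization(OTHERWISE, "none", 0)


def conditional_table(
    rows: Iterable[tuple[int, int]],
) -> dict[int, Optional[tuple[float, int]]]:
    """Pr(correct | charmatch) from (charmatch, gold) rows.

    Returns {0: (proportion, stratum size) | None, 1: ...}; an empty
    stratum is reported as None (undefined), never as 0.
    """
    strata: dict[int, list[int]] = {0: [], 1: []}
    for cm, gold in rows:
        strata[int(cm)].append(int(gold))
    out: dict[int, Optional[tuple[float, int]]] = {}
    for cm in (0, 1):
        golds = strata[cm]
        out[cm] = (sum(golds) / len(golds), len(golds)) if golds else None
    return out


def rank_histogram(rows: Iterable[tuple[int, int]]) -> dict[int, int]:
    """# correct by n-best rank, from (rank, gold) rows; zero ranks included."""
    hist: dict[int, int] = {}
    max_rank = -1
    for rank, gold in rows:
        max_rank = max(max_rank, rank)
        if gold:
            hist[rank] = hist.get(rank, 0) + 1
    return {r: hist.get(r, 0) for r in range(max_rank + 1)}


# -- CART-style decision tree ----------------------------------------------

@dataclass
class TreeNode:
    """One tree node with the reporting triple (label, accuracy, coverage)."""

    best_label: int
    accuracy: float
    coverage: float  # fraction of the root's rows reaching this node
    feature: Optional[str] = None  # None for a leaf
    threshold: Optional[float] = None  # split: feature <= threshold goes left
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        head = (
            f"{pad}label={self.best_label} acc={self.accuracy:.2f} "
            f"cov={100 * self.coverage:.1f}%"
        )
        if self.is_leaf:
            return head + " [leaf]\n"
        out = head + f" split: {self.feature} <= {self.threshold:g}\n"
        out += self.left.render(indent + 1)
        out += self.right.render(indent + 1)
        return out


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


class GiniDecisionTree(BaseEstimator):
    """Greedy binary CART on Gini impurity over named features.

    Binary features split as equality tests; the integer ``rank`` splits
    as threshold tests (rank <= t).  Recursion stops at ``max_depth``,
    ``min_leaf`` rows, or a pure node.  Fitted attribute ``tree_`` is the
    root :class:`TreeNode`.
    """

    def __init__(self, features: Sequence[str] = (), max_depth: int = 4, min_leaf: int = 20):
        self.features = features
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def fit(self, X: pd.DataFrame, y) -> "GiniDecisionTree":
        features = list(self.features) or list(X.columns)
        if not features:
            raise ValueError("empty feature subset")
        missing = [f for f in features if f not in X.columns]
        if missing:
            raise ValueError(f"features not in X: {missing}")
        Xm = X[features].to_numpy(dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if y.size == 0:
            raise ValueError("empty training data")
        self.feature_names_ = features
        self.tree_ = self._grow(Xm, y, depth=0, n_root=y.size)
        return self

    def _node_stats(self, y: np.ndarray, n_root: int) -> tuple[int, float, float]:
        ones = int(y.sum())
        best = 1 if ones * 2 > y.size else 0
        acc = (ones if best == 1 else y.size - ones) / y.size
        return best, acc, y.size / n_root

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int, n_root: int) -> TreeNode:
        best_label, acc, cov = self._node_stats(y, n_root)
        node = TreeNode(best_label, acc, cov)
        if depth >= self.max_depth or y.size < 2 * self.min_leaf or len(np.unique(y)) == 1:
            return node

        parent_gini = _gini(y)
        best = None  # (weighted_gini, feat_idx, threshold, mask)
        for j, name in enumerate(self.feature_names_):
            values = np.unique(X[:, j])
            thresholds = (values[:-1] + values[1:]) / 2.0 if values.size > 1 else []
            for t in thresholds:
                mask = X[:, j] <= t
                nl, nr = int(mask.sum()), int((~mask).sum())
                if nl < self.min_leaf or nr < self.min_leaf:
                    continue
                g = (nl * _gini(y[mask]) + nr * _gini(y[~mask])) / y.size
                if best is None or g < best[0] - 1e-12:
                    best = (g, j, float(t), mask)
        if best is None or best[0] >= parent_gini - 1e-12:
            return node

        _, j, t, mask = best
        node.feature = self.feature_names_[j]
        node.threshold = t
        node.left = self._grow(X[mask], y[mask], depth + 1, n_root)
        node.right = self._grow(X[~mask], y[~mask], depth + 1, n_root)
        return node

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xm = X[self.feature_names_].to_numpy(dtype=float)
        idx = {f: j for j, f in enumerate(self.feature_names_)}
        out = np.empty(Xm.shape[0], dtype=int)
        for i in range(Xm.shape[0]):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if Xm[i, idx[node.feature]] <= node.threshold else node.right
            out[i] = node.best_label
        return out


def fit_tree(
    rows: pd.DataFrame,
    formula: Sequence[str],
    gold_column: str = "gold",
    max_depth: int = 4,
    min_leaf: int = 20,
) -> TreeNode:
    """Fit a Gini tree of ``gold ~ formula`` on a feature table; returns the root."""
    if not list(formula):
        raise ValueError("empty feature subset")
    est = GiniDecisionTree(features=list(formula), max_depth=max_depth, min_leaf=min_leaf)
    est.fit(rows, rows[gold_column])
    return est.tree_


def level_coverages(root: TreeNode) -> list[float]:
    """Total coverage per tree level (each should sum to the root's, i.e. 1)."""
    totals: list[float] = []
    frontier = [root]
    while frontier:
        totals.append(sum(n.coverage for n in frontier))
        nxt = []
        for n in frontier:
            if not n.is_leaf:
                nxt.extend([n.left, n.right])
            else:
                nxt.append(n)  # a leaf persists through lower levels
        if all(n.is_leaf for n in frontier):
            break
        frontier = nxt
    return totals
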