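"""Descriptor-based structure-activity classifier: entropy filter + decision forest.

Molecular-descriptor columns with little information content (by Shannon
entropy of their discretized values) are removed first.  The classifier is a
five-tree decision forest: binary CART trees split on Gini impurity
decrease, and the trees are kept *distinct* by excluding every descriptor
used by earlier trees from later ones, so the five trees read disjoint
descriptor sets while voting on the same compounds.  The forest prediction
is the unweighted mean of the per-tree leaf class fractions.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_TREES = 5
DEFAULT_MIN_LEAF = 5
DEFAULT_MIN_ENTROPY = 1.0  # bits
ENTROPY_BINS = 10


def shannon_entropy(column, bins: int = ENTROPY_BINS) -> float:
    """Entropy (bits) of a descriptor column after discretization.

    Columns with at most ``bins`` distinct values are treated as categorical;
    continuous columns are discretized into ``bins`` equal-width intervals.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("empty column")
    uniq = np.unique(x)
    if uniq.size <= 1:
        return 0.0
    if uniq.size <= bins:
        _, counts = np.unique(x, return_counts=True)
    else:
        counts, _ = np.histogram(x, bins=bins)
        counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def filter_descriptors(table: pd.DataFrame, min_entropy: float = DEFAULT_MIN_ENTROPY) -> pd.DataFrame:
    """Keep descriptor columns with entropy >= ``min_entropy`` bits."""
    ent = table.apply(shannon_entropy, axis=0)
    kept = ent.index[ent >= min_entropy]
    if len(kept) == 0:
        raise ValueError("entropy filter removed every descriptor column")
    return table[kept]


@dataclass
class TreeNode:
    n_potent: int
    n_weak: int
    descriptor: str | None = None
    threshold: float | None = None
    gini_decrease: float | None = None
    left: "TreeNode | None" = None  # value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.descriptor is None

    @property
    def p_potent(self) -> float:
        total = self.n_potent + self.n_weak
        return self.n_potent / total if total else 0.5

    def predict_row(self, row: pd.Series) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.descriptor] <= node.threshold else node.right
        return node.p_potent

    def descriptors(self) -> set[str]:
        if self.is_leaf:
            return set()
        return {self.descriptor} | self.left.descriptors() | self.right.descriptors()

    def to_dict(self) -> dict:
        d = {"n_potent": self.n_potent, "n_weak": self.n_weak}
        if not self.is_leaf:
            d.update(
                descriptor=self.descriptor,
                threshold=self.threshold,
                gini_decrease=self.gini_decrease,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n_potent=d["n_potent"], n_weak=d["n_weak"])
        if "descriptor" in d:
            node.descriptor = d["descriptor"]
            node.threshold = d["threshold"]
            node.gini_decrease = d["gini_decrease"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _gini(n_pot: int, n_weak: int) -> float:
    n = n_pot + n_weak
    if n == 0:
        return 0.0
    p = n_pot / n
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray, col_names: list[str], min_leaf: int):
    """Exhaustive best (descriptor, threshold) by weighted Gini decrease.

    Thresholds are midpoints of consecutive distinct sorted values.  Ties are
    broken by column order, then by the smaller threshold.
    """
    n = len(y)
    n_pot = int(y.sum())
    parent = _gini(n_pot, n - n_pot)
    best = None  # (decrease, col_idx, threshold)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        xs, ys = X[order, j], y[order]
        cum_pot = np.cumsum(ys)
        idx = np.arange(1, n)
        distinct = xs[1:] != xs[:-1]
        valid = distinct & (idx >= min_leaf) & (n - idx >= min_leaf)
        if not valid.any():
            continue
        nl = idx[valid]
        pot_l = cum_pot[:-1][valid]
        nr = n - nl
        pot_r = n_pot - pot_l
        pl, pr = pot_l / nl, pot_r / nr
        child = (nl * 2 * pl * (1 - pl) + nr * 2 * pr * (1 - pr)) / n
        dec = parent - child
        i_best = int(np.argmax(dec))
        if dec[i_best] > 1e-12:
            thr = 0.5 * (xs[nl[i_best] - 1] + xs[nl[i_best]])
            cand = (float(dec[i_best]), j, float(thr))
            if best is None or cand[0] > best[0] + 1e-15:
                best = cand
    return best


def build_tree(
    table: pd.DataFrame,
    labels,
    excluded_descriptors: set[str] | None = None,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> TreeNode:
    """Grow one binary Gini tree; growth stops at purity, min_leaf, or no gain."""
    excluded = set(excluded_descriptors or ())
    cols = [c for c in table.columns if c not in excluded]
    if not cols:
        raise ValueError("no descriptors available (all excluded)")
    y = np.asarray([1 if str(v).upper() in ("1", "P", "POTENT", "TRUE") else 0 for v in np.asarray(labels)])
    X = table[cols].to_numpy(dtype=float)

    def grow(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        node = TreeNode(n_potent=int(yi.sum()), n_weak=int(len(yi) - yi.sum()))
        if node.n_potent == 0 or node.n_weak == 0 or len(idx) < 2 * min_leaf:
            return node
        split = _best_split(X[idx], yi, cols, min_leaf)
        if split is None:
            return node
        dec, j, thr = split
        mask = X[idx, j] <= thr
        node.descriptor = cols[j]
        node.threshold = thr
        node.gini_decrease = dec
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return grow(np.arange(len(y)))


@dataclass
class ForestModel:
    trees: list[TreeNode]
    descriptor_sets: list[set[str]]
    flags: list[str] = field(default_factory=list)

    def predict_proba(self, table: pd.DataFrame) -> pd.Series:
        """Mean of the per-tree leaf potent fractions, per compound."""
        votes = np.zeros(len(table))
        for tree in self.trees:
            votes += np.array([tree.predict_row(row) for _, row in table.iterrows()])
        return pd.Series(votes / len(self.trees), index=table.index, name="p_potent")

    def predict(self, table: pd.DataFrame, cutoff: float = 0.5) -> pd.Series:
        p = self.predict_proba(table)
        return pd.Series(np.where(p >= cutoff, "P", "W"), index=table.index, name="call")

    def usage(self) -> Counter:
        """Number of this model's trees using each descriptor (0 or 1 by disjointness)."""
        c: Counter = Counter()
        for s in self.descriptor_sets:
            c.update(s)
        return c

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"trees": [t.to_dict() for t in self.trees], "flags": self.flags}, indent=2) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ForestModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        trees = [TreeNode.from_dict(t) for t in d["trees"]]
        return cls(trees=trees, descriptor_sets=[t.descriptors() for t in trees], flags=list(d.get("flags", [])))


def train_forest(
    table: pd.DataFrame,
    labels,
    n_trees: int = N_TREES,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> ForestModel:
    """Five sequential Gini trees on pairwise-disjoint descriptor sets."""
    excluded: set[str] = set()
    trees: list[TreeNode] = []
    sets: list[set[str]] = []
    flags: list[str] = []
    for t in range(n_trees):
        try:
            tree = build_tree(table, labels, excluded_descriptors=excluded, min_leaf=min_leaf)
        except ValueError:
            flags.append(f"only {len(trees)} trees could be grown before descriptors ran out")
            break
        used = tree.descriptors()
        if not used:
            flags.append(f"tree {t + 1} found no informative split; forest truncated at {len(trees)} trees")
            break
        trees.append(tree)
        sets.append(used)
        excluded |= used
    if not trees:
        raise ValueError("no tree found an informative split")
    return ForestModel(trees=trees, descriptor_sets=sets, flags=flags)


def usage_tally(models: list[ForestModel]) -> Counter:
    """Across models, the number of trees in which each descriptor was used."""
    if not models:
        raise ValueError("need at least one model")
    total: Counter = Counter()
    for m in models:
        total.update(m.usage())
    return total
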