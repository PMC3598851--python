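"""Bipartition algebra: majority-rule consensus, Robinson-Foulds
comparison with false-positive/false-negative decomposition, and the
Gamma-scale calibration curve fit.

A bipartition is the pair of leaf blocks induced by deleting an
internal edge of an unrooted tree; it is stored canonically as the
frozenset block NOT containing a fixed reference leaf (the
lexicographically smallest label).  Trivial splits that isolate a
single leaf carry no topological information and are excluded from
every count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import TreeError, leaf_labels, read_newick

Bipartition = frozenset


class ConsensusError(ValueError):
    pass


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    A fully resolved unrooted binary tree on n leaves yields n - 3.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    ref = min(labels)
    splits: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        block = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(block) < 2 or len(block) > n - 2:
            continue
        if ref in block:
            block = frozenset(labels - block)
        if len(block) >= 2:
            splits.add(block)
    return splits


def _compatible(a: Bipartition, b: Bipartition, labels: set[str]) -> bool:
    """Two splits are compatible iff some pairing of their blocks is disjoint."""
    a2, b2 = labels - a, labels - b
    return (not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2))


def majority_consensus(trees: list[dendropy.Tree],
                       min_freq: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: splits in strictly more than half the trees.

    Splits occurring in a strict majority are pairwise compatible, so
    the consensus always exists; it may be multifurcating.  Exact-50%
    splits are excluded.
    """
    if not trees:
        raise ConsensusError("need at least one tree")
    labels = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != labels:
            raise ConsensusError("trees have mismatched leaf sets")
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    cutoff = min_freq * len(trees)
    majority = [bp for bp, c in counts.items() if c > cutoff]
    # nest larger blocks first so parents are in place before children
    majority.sort(key=lambda bp: (-len(bp), sorted(bp)))
    return _tree_from_splits(labels, majority)


def _tree_from_splits(labels: set[str], splits: list[Bipartition]) -> dendropy.Tree:
    """Build a (possibly multifurcating) tree from nested compatible splits."""
    root: dict = {"children": {lf: None for lf in sorted(labels)}}

    def leaves_under(node: dict | str) -> set[str]:
        if isinstance(node, str):
            return {node}
        out: set[str] = set()
        for key, child in node["children"].items():
            out |= leaves_under(child) if child is not None else {key}
        return out

    def insert(node: dict, block: set[str]) -> bool:
        grouped = {}
        covered: set[str] = set()
        for key, child in list(node["children"].items()):
            under = leaves_under(child) if child is not None else {key}
            if under <= block:
                grouped[key] = child
                covered |= under
            elif under & block:
                return child is not None and insert(child, block)
        if covered != block:
            return False
        new_child = {"children": grouped}
        for key in grouped:
            del node["children"][key]
        node["children"][f"__clade_{id(new_child)}"] = new_child
        return True

    for bp in splits:
        insert(root, set(bp))

    def to_newick(node: dict | None, key: str) -> str:
        if node is None:
            return key
        inner = ",".join(to_newick(c, k) for k, c in node["children"].items())
        return f"({inner})"

    newick = to_newick(root, "") + ";"
    return read_newick(newick, is_path=False)


@dataclass
class TreeComparison:
    """Bipartition-level confusion counts of an inferred tree vs a reference."""

    tp: int
    fp: int
    fn: int
    precision_defined: bool = True

    @property
    def rf(self) -> int:
        return self.fp + self.fn

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0  # star tree: no asserted splits, none wrong
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0
        return self.tp / (self.tp + self.fn)


def compare_trees(inferred: dendropy.Tree,
                  reference: dendropy.Tree) -> TreeComparison:
    """TP/FP/FN over non-trivial bipartitions; RF distance = FP + FN."""
    if leaf_labels(inferred) != leaf_labels(reference):
        raise ConsensusError("trees have mismatched leaf sets")
    inf_bp = bipartitions(inferred)
    ref_bp = bipartitions(reference)
    tp = len(inf_bp & ref_bp)
    fp = len(inf_bp - ref_bp)
    fn = len(ref_bp - inf_bp)
    return TreeComparison(tp=tp, fp=fp, fn=fn,
                          precision_defined=(tp + fp) > 0)


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    return compare_trees(a, b).rf


# ---------------------------------------------------------------------------
# Gamma-scale calibration

def fit_theta_curve(thetas: np.ndarray, mean_rf: np.ndarray,
                    degree: int = 4) -> tuple[float, np.poly1d]:
    """Fit mean RF distance vs theta to a polynomial; return its minimiser.

    The minimum is taken over the fitted curve restricted to the grid
    interval.  A flat fitted curve returns the interval lower bound
    with a tie warning.
    """
    thetas = np.asarray(thetas, dtype=float)
    mean_rf = np.asarray(mean_rf, dtype=float)
    if len(thetas) < degree + 2:
        raise ConsensusError(
            f"need at least degree+2 = {degree + 2} grid points, "
            f"got {len(thetas)}")
    coeffs = np.polyfit(thetas, mean_rf, degree)
    poly = np.poly1d(coeffs)
    lo, hi = float(thetas.min()), float(thetas.max())
    candidates = [lo, hi]
    for r in poly.deriv().roots:
        if abs(r.imag) < 1e-9 and lo <= r.real <= hi:
            candidates.append(float(r.real))
    values = poly(candidates)
    if np.ptp(values) < 1e-12:
        warnings.warn("flat calibration curve; returning interval lower bound")
        return lo, poly
    return float(candidates[int(np.argmin(values))]), poly


def calibrate_theta(families, theta_grid, replicates: int = 100,
                    poly_degree: int = 4, seed: int = 0,
                    tree_method: str = "bme_nni"):
    """Run the full pipeline over a theta grid and locate the optimum.

    ``families`` is a list of (SequenceSet, reference dendropy.Tree)
    pairs.  For each theta the replicate-consensus pipeline runs on
    every family and the mean RF distance to the references is
    recorded; the grid is then fit with :func:`fit_theta_curve`.
    Returns (theta_opt, table) where table is a pandas DataFrame with
    columns theta, mean_rf, mean_fp, mean_fn.
    """
    import pandas as pd

    from .pipeline import consensus_for_family

    rows = []
    for theta in theta_grid:
        rfs, fps, fns = [], [], []
        for fam_idx, (seqs, ref) in enumerate(families):
            cons = consensus_for_family(
                seqs, theta=theta, replicates=replicates,
                seed=seed + 7919 * fam_idx, tree_method=tree_method)
            cmp_ = compare_trees(cons, ref)
            rfs.append(cmp_.rf)
            fps.append(cmp_.fp)
            fns.append(cmp_.fn)
        rows.append((float(theta), float(np.mean(rfs)),
                     float(np.mean(fps)), float(np.mean(fns))))
    table = pd.DataFrame(rows, columns=["theta", "mean_rf", "mean_fp", "mean_fn"])
    theta_opt, _ = fit_theta_curve(table["theta"].to_numpy(),
                                   table["mean_rf"].to_numpy(),
                                   degree=poly_degree)
    return theta_opt, table
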