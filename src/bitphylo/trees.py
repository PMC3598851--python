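"""Distance-based tree inference: neighbour joining and balanced
minimum evolution with NNI refinement.

Both methods are implemented directly on the distance matrix.  The
balanced-ME path starts from the NJ topology and applies
nearest-neighbour-interchange moves in steepest-descent order until no
move reduces the balanced tree length (the Pauplin estimate, in which
each pairwise distance is weighted by 2 to the minus the number of
internal nodes on the connecting path).  Trees are carried as dendropy
objects so Newick round-trips, consensus and reporting all share one
container.
"""

from __future__ import annotations

import sys
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix

TAXON_NAMESPACE_KW = dict(suppress_internal_node_taxa=True)


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(source: str | Path, *, is_path: bool = True) -> dendropy.Tree:
    """Parse a Newick tree (from a path, or a string with is_path=False)."""
    try:
        if is_path:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree) + "\n")


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Internal unrooted-graph representation used by the inference engines.
# Leaves are 0..n-1 (indexing DistanceMatrix ids); internal nodes n, n+1, ...

class _Graph:
    def __init__(self, n_leaves: int):
        self.n = n_leaves
        self.adj: dict[int, set[int]] = {}
        self.lengths: dict[frozenset[int], float] = {}
        self.next_id = n_leaves

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)
        self.lengths[frozenset((u, v))] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.lengths.pop(frozenset((u, v)), None)

    def new_internal(self) -> int:
        node = self.next_id
        self.next_id += 1
        self.adj[node] = set()
        return node

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                e = frozenset((u, v))
                if e not in seen:
                    seen.add(e)
                    yield u, v

    def internal_edges(self):
        for u, v in self.edges():
            if u >= self.n and v >= self.n:
                yield u, v

    def to_newick(self, ids: list[str]) -> str:
        # root the traversal at an internal node for unrooted output
        root = next((x for x in self.adj if x >= self.n), 0)

        def fmt(node: int, parent: int) -> str:
            length = self.lengths.get(frozenset((node, parent)), 0.0)
            if node < self.n:
                return f"{ids[node]}:{length:.10g}"
            inner = ",".join(fmt(c, node) for c in sorted(self.adj[node])
                             if c != parent)
            return f"({inner}):{length:.10g}"

        children = ",".join(fmt(c, root) for c in sorted(self.adj[root]))
        return f"({children});"


# ---------------------------------------------------------------------------
# Neighbour joining

def _nj_graph(d: np.ndarray) -> _Graph:
    n = d.shape[0]
    g = _Graph(n)
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    node_of = {i: i for i in range(n)}  # cluster key -> graph node

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = dist[i, j] / 2.0 + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dist[i, j] - li
        u = g.new_internal()
        g.add_edge(node_of[i], u, max(li, 0.0))
        g.add_edge(node_of[j], u, max(lj, 0.0))
        new_key = u
        node_of[new_key] = u
        for k in active:
            if k in (i, j):
                continue
            dk = (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
            dist[new_key, k] = dist[k, new_key] = dk
        active = [k for k in active if k not in (i, j)] + [new_key]

    i, j, k = active
    u = g.new_internal()
    li = (dist[i, j] + dist[i, k] - dist[j, k]) / 2.0
    lj = (dist[i, j] + dist[j, k] - dist[i, k]) / 2.0
    lk = (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
    g.add_edge(node_of[i], u, max(li, 0.0))
    g.add_edge(node_of[j], u, max(lj, 0.0))
    g.add_edge(node_of[k], u, max(lk, 0.0))
    return g


# ---------------------------------------------------------------------------
# Balanced minimum evolution

def _balanced_weights(g: _Graph) -> dict[tuple[int, int], np.ndarray]:
    """Balanced leaf-weight vector for every directed edge (u, v).

    The vector describes the subtree on the v side: a leaf is an
    indicator; an internal node averages its two child vectors, halving
    weights at each branching, which is exactly the balanced scheme.
    """
    w: dict[tuple[int, int], np.ndarray] = {}

    def vec(u: int, v: int) -> np.ndarray:
        key = (u, v)
        if key in w:
            return w[key]
        if v < g.n:
            out = np.zeros(g.n)
            out[v] = 1.0
        else:
            children = [c for c in g.adj[v] if c != u]
            out = sum(vec(v, c) for c in children) / len(children)
        w[key] = out
        return out

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * g.next_id + 100))
    try:
        for u, v in g.edges():
            vec(u, v)
            vec(v, u)
    finally:
        sys.setrecursionlimit(old)
    return w


def balanced_tree_length(g: _Graph, d: np.ndarray) -> float:
    """Pauplin balanced length: sum over pairs of 2^-p(i,j) d(i,j)."""
    # topological internal-node counts via BFS from each leaf
    total = 0.0
    for i in range(g.n):
        depth = {i: 0}
        stack = [(i, None)]
        while stack:
            node, parent = stack.pop()
            for nb in g.adj[node]:
                if nb == parent:
                    continue
                depth[nb] = depth[node] + (1 if node >= g.n else 0)
                stack.append((nb, node))
        for j in range(i + 1, g.n):
            # depth[j] = number of internal nodes on the i..j path
            total += d[i, j] * 2.0 ** (-depth[j])
    return total


def _nni_pass(g: _Graph, d: np.ndarray) -> bool:
    """Apply the single best improving NNI; True if a move was made."""
    w = _balanced_weights(g)

    def delta(x: np.ndarray, y: np.ndarray) -> float:
        return float(x @ d @ y)

    best_gain, best_move = 0.0, None
    for u, v in g.internal_edges():
        a1, a2 = sorted(c for c in g.adj[u] if c != v)
        b1, b2 = sorted(c for c in g.adj[v] if c != u)
        A, B = w[(u, a1)], w[(u, a2)]
        C, D = w[(v, b1)], w[(v, b2)]
        d_ab, d_cd = delta(A, B), delta(C, D)
        d_ac, d_bd = delta(A, C), delta(B, D)
        d_ad, d_bc = delta(A, D), delta(B, C)
        base = d_ab + d_cd
        # swap a2 <-> b1 yields split {A,C} | {B,D}
        gain1 = (base - (d_ac + d_bd)) / 4.0
        # swap a2 <-> b2 yields split {A,D} | {B,C}
        gain2 = (base - (d_ad + d_bc)) / 4.0
        for gain, move in ((gain1, (u, a2, v, b1)), (gain2, (u, a2, v, b2))):
            if gain > best_gain + 1e-12:
                best_gain, best_move = gain, move
    if best_move is None:
        return False
    u, x, v, y = best_move
    g.remove_edge(u, x)
    g.remove_edge(v, y)
    g.add_edge(u, y)
    g.add_edge(v, x)
    return True


def _balanced_branch_lengths(g: _Graph, d: np.ndarray) -> None:
    """Balanced least-squares branch-length estimates, clamped at 0."""
    w = _balanced_weights(g)

    def delta(x: np.ndarray, y: np.ndarray) -> float:
        return float(x @ d @ y)

    for u, v in g.edges():
        if u < g.n or v < g.n:
            leaf, hub = (u, v) if u < g.n else (v, u)
            others = [c for c in g.adj[hub] if c != leaf]
            x = w[(hub, leaf)]
            if len(others) == 1:  # degenerate (should not occur unrooted)
                length = delta(x, w[(hub, others[0])])
            else:
                subs = [w[(hub, c)] for c in others]
                length = 0.0
                pairs = 0
                for ai in range(len(subs)):
                    for bi in range(ai + 1, len(subs)):
                        a, b = subs[ai], subs[bi]
                        length += (delta(x, a) + delta(x, b) - delta(a, b)) / 2.0
                        pairs += 1
                length /= pairs
        else:
            a1, a2 = sorted(c for c in g.adj[u] if c != v)
            b1, b2 = sorted(c for c in g.adj[v] if c != u)
            A, B = w[(u, a1)], w[(u, a2)]
            C, D = w[(v, b1)], w[(v, b2)]
            length = (delta(A, C) + delta(A, D) + delta(B, C) + delta(B, D)) / 4.0 \
                - (delta(A, B) + delta(C, D)) / 2.0
        g.lengths[frozenset((u, v))] = max(length, 0.0)


def infer_tree(d: DistanceMatrix, method: str = "bme_nni") -> dendropy.Tree:
    """Infer a strictly bifurcating unrooted tree from distances.

    ``nj`` runs plain neighbour joining; ``bme_nni`` refines the NJ
    topology by NNI under the balanced minimum-evolution criterion and
    re-estimates branch lengths with balanced averages.  Negative
    branch-length estimates are clamped to zero.
    """
    if d.n < 4:
        raise TreeError(f"tree inference requires >= 4 taxa, got {d.n}")
    if not np.all(np.isfinite(d.values)):
        raise TreeError("non-finite distances")
    g = _nj_graph(d.values)
    if method == "bme_nni":
        while _nni_pass(g, d.values):
            pass
        _balanced_branch_lengths(g, d.values)
    elif method != "nj":
        raise ValueError(f"unknown method {method!r}")
    return read_newick(g.to_newick(d.ids), is_path=False)


def bme_length(tree: dendropy.Tree, d: DistanceMatrix) -> float:
    """Balanced (Pauplin) tree length of an arbitrary tree under d."""
    g = _graph_from_tree(tree, d.ids)
    return balanced_tree_length(g, d.values)


def _graph_from_tree(tree: dendropy.Tree, ids: list[str]) -> _Graph:
    index = {label: i for i, label in enumerate(ids)}
    g = _Graph(len(ids))
    g.next_id = len(ids)
    node_map: dict[dendropy.Node, int] = {}

    tree = tree.clone(depth=1)
    tree.is_rooted = False

    def node_id(nd: dendropy.Node) -> int:
        if nd not in node_map:
            if nd.is_leaf():
                node_map[nd] = index[nd.taxon.label]
            else:
                node_map[nd] = g.new_internal()
        return node_map[nd]

    seed = tree.seed_node
    # suppress a degree-2 seed node (rooted newick input)
    for nd in tree.preorder_node_iter():
        u = node_id(nd)
        for ch in nd.child_nodes():
            v = node_id(ch)
            g.add_edge(u, v, ch.edge.length or 0.0)
    su = node_id(seed)
    if len(g.adj[su]) == 2:
        a, b = g.adj[su]
        la = g.lengths[frozenset((su, a))]
        lb = g.lengths[frozenset((su, b))]
        g.remove_edge(su, a)
        g.remove_edge(su, b)
        del g.adj[su]
        g.add_edge(a, b, la + lb)
    return g
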