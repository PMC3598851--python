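"""Synthetic protein families: random trees and sequences evolved
along them under a reversible continuous-time substitution process.

The simulator provides known reference topologies so topology
recovery, the perturbation model and the consensus machinery can all
be exercised without external data.  It is deliberately simple — no
indels by default, a single stationary composition, optional Gamma
rate variation across sites — so conclusions drawn from it are about
the inference machinery, not about realism of protein evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .perturbation import AA_ORDER
from .sequences import ProteinSequence, SequenceSet
from .trees import read_newick


class SimulationError(ValueError):
    pass


#: BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff),
#: ordered as AA_ORDER; used as the stationary composition.
BLOSUM62_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic protein-family simulation.

    Branch lengths are in expected substitutions per site.  The rate
    model is reversible: exchangeabilities are either derived from
    BLOSUM62 odds (2**(B(i,j)/2), default) or flat; the stationary
    composition is the BLOSUM62 background.  ``gamma_shape`` switches
    on Gamma(shape, mean 1) rate multipliers across sites.
    """

    n_taxa: int = 12
    length: int = 300
    branch_length_mean: float = 0.15
    rate_model: str = "blosum62"  # or "flat"
    gamma_shape: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise SimulationError("n_taxa must be >= 4")
        if self.length < 1:
            raise SimulationError("length must be >= 1")
        if self.branch_length_mean <= 0:
            raise SimulationError("branch_length_mean must be > 0")


def random_tree(n_taxa: int, branch_length_mean: float = 0.15,
                seed: int | np.random.Generator = 0,
                labels: list[str] | None = None) -> dendropy.Tree:
    """Uniform random unrooted binary topology via sequential addition.

    Starting from the 3-taxon star, each remaining taxon is attached to
    an edge chosen uniformly at random, which makes all (2n-5)!!
    unrooted binary topologies equally likely.  Branch lengths are
    i.i.d. exponential with the given mean.
    """
    if n_taxa < 4:
        raise SimulationError("need at least 4 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = labels or [f"t{i}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise SimulationError("labels length must equal n_taxa")
    # edges as a list of [child_newick_fragment] pairs; simpler: grow an
    # adjacency structure with leaves 0..n-1 and internal nodes n, n+1, ...
    adj: dict[int, set[int]] = {i: set() for i in range(3)}
    nxt = n_taxa
    center = nxt
    nxt += 1
    adj[center] = set()
    edges: list[tuple[int, int]] = []
    for leaf in range(3):
        adj[center].add(leaf)
        adj[leaf].add(center)
        edges.append((leaf, center))
    for leaf in range(3, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        mid = nxt
        nxt += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[mid] = {u, v, leaf}
        adj[u].add(mid)
        adj[v].add(mid)
        adj[leaf] = {mid}
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (leaf, mid)])

    lengths = {frozenset(e): rng.exponential(branch_length_mean) for e in edges}

    def fmt(node: int, parent: int) -> str:
        length = lengths[frozenset((node, parent))]
        if node < n_taxa:
            return f"{labels[node]}:{length:.10g}"
        inner = ",".join(fmt(c, node) for c in sorted(adj[node]) if c != parent)
        return f"({inner}):{length:.10g}"

    newick = "(" + ",".join(fmt(c, center) for c in sorted(adj[center])) + ");"
    return read_newick(newick, is_path=False)


def random_ultrametric_tree(n_taxa: int, height: float = 0.5,
                            seed: int | np.random.Generator = 0,
                            labels: list[str] | None = None) -> dendropy.Tree:
    """Random topology with clock-like branch lengths (all leaves at
    distance ``height`` from the root)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = labels or [f"t{i}" for i in range(n_taxa)]
    base = random_tree(n_taxa, 1.0, rng, labels)
    base.is_rooted = True
    # reroot at an internal node, then assign node heights top-down
    base.reroot_at_node(base.seed_node, update_bipartitions=False)

    def assign(node, top: float) -> None:
        for ch in node.child_nodes():
            if ch.is_leaf():
                ch.edge.length = top
            else:
                h = top * rng.uniform(0.3, 0.8)
                ch.edge.length = top - h
                assign(ch, h)

    assign(base.seed_node, height)
    base.is_rooted = False
    return base


def _rate_matrix(model: str) -> tuple[np.ndarray, np.ndarray]:
    """Reversible rate matrix Q (rows sum to 0, mean rate 1) and its
    stationary distribution pi."""
    pi = np.array([BLOSUM62_FREQS[a] for a in AA_ORDER])
    pi /= pi.sum()
    n = len(AA_ORDER)
    if model == "flat":
        ex = np.ones((n, n))
    elif model == "blosum62":
        b = substitution_matrices.load("BLOSUM62")
        ex = np.array([[2.0 ** (b[i, j] / 2.0) for j in AA_ORDER]
                       for i in AA_ORDER])
    else:
        raise SimulationError(f"unknown rate model {model!r}")
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale, pi


def evolve_sequences(tree: dendropy.Tree,
                     config: SimulationConfig) -> SequenceSet:
    """Evolve a protein family down ``tree``; returns the leaf sequences.

    The root sequence is drawn from the stationary composition; each
    branch applies exp(Q * rate * length) site-wise.  Site rates are 1
    or Gamma(shape, mean 1) multipliers when configured.
    """
    rng = np.random.default_rng(config.seed)
    q, pi = _rate_matrix(config.rate_model)
    evals, evecs = np.linalg.eig(q)
    inv = np.linalg.inv(evecs)

    def transition(t: float) -> np.ndarray:
        p = (evecs * np.exp(evals * t)) @ inv
        p = np.real(p)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    if config.gamma_shape is not None:
        rates = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape,
                          size=config.length)
    else:
        rates = np.ones(config.length)

    work = tree.clone(depth=1)
    work.is_rooted = True
    root = work.seed_node
    root_seq = rng.choice(20, size=config.length, p=pi)
    states: dict = {root: root_seq}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in work.preorder_node_iter():
        if node is root:
            seq = root_seq
        else:
            parent_seq = states[node.parent_node]
            t = node.edge.length or 0.0
            if t == 0:
                seq = parent_seq.copy()
            else:
                seq = parent_seq.copy()
                for r in np.unique(rates):
                    p = transition(t * r)
                    site_mask = rates == r
                    cum = p.cumsum(axis=1)
                    u = rng.random(site_mask.sum())
                    rows = cum[parent_seq[site_mask]]
                    seq[site_mask] = (u[:, None] > rows).sum(axis=1)
            states[node] = seq
        if node.is_leaf():
            leaves.append((node.taxon.label, seq))
    aa = np.array(list(AA_ORDER))
    out = [ProteinSequence(label, "".join(aa[s])) for label, s in leaves]
    return SequenceSet(out)


def simulate_family(config: SimulationConfig):
    """Random tree + evolved family; returns (SequenceSet, reference tree)."""
    rng = np.random.default_rng(config.seed)
    tree = random_tree(config.n_taxa, config.branch_length_mean,
                       np.random.default_rng(rng.integers(2 ** 31)))
    seq_config = SimulationConfig(
        n_taxa=config.n_taxa, length=config.length,
        branch_length_mean=config.branch_length_mean,
        rate_model=config.rate_model, gamma_shape=config.gamma_shape,
        seed=int(rng.integers(2 ** 31)))
    seqs = evolve_sequences(tree, seq_config)
    return seqs, tree


def additive_distance_matrix(tree: dendropy.Tree):
    """Exact path-length (additive) distances between leaves of a tree."""
    from .distances import DistanceMatrix

    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids, values)
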