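import itertools

import numpy as np
import pytest

from bitphylo.consensus import bipartitions, robinson_foulds
from bitphylo.distances import DistanceMatrix
from bitphylo.simulate import additive_distance_matrix, random_tree
from bitphylo.trees import (TreeError, as_newick, bme_length, infer_tree,
                            leaf_labels, read_newick, write_newick)


def four_taxon_matrix(topology, internal=2.0, external=1.0):
    """Additive distances for one of the 3 unrooted 4-taxon topologies."""
    ids = list("abcd")
    pairings = {"ab|cd": ("a", "b"), "ac|bd": ("a", "c"), "ad|bc": ("a", "d")}
    x, y = pairings[topology]
    rest = [i for i in ids if i not in (x, y)]
    v = np.full((4, 4), 2 * external + internal)
    np.fill_diagonal(v, 0.0)
    for pair in ((x, y), tuple(rest)):
        i, j = ids.index(pair[0]), ids.index(pair[1])
        v[i, j] = v[j, i] = 2 * external
    return DistanceMatrix(ids, v)


def ls_best_topology(d):
    """Independent oracle: least-squares fit of all 3 labelled topologies."""
    best, best_err = None, np.inf
    for topo in ("ab|cd", "ac|bd", "ad|bc"):
        # 5 branch lengths, solved by least squares on the 6 path equations
        pairs = list(itertools.combinations("abcd", 2))
        cherry = set(topo.split("|")[0])
        rows, rhs = [], []
        for a, b in pairs:
            row = [0.0] * 5  # ea, eb, ec, ed, internal
            row["abcd".index(a)] = 1.0
            row["abcd".index(b)] = 1.0
            same_side = ({a, b} == cherry) or ({a, b} == set("abcd") - cherry)
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            rhs.append(d.value(a, b))
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        err = float(res[0]) if len(res) else 0.0
        if err < best_err:
            best_err, best = err, topo
    return best


@pytest.mark.parametrize("method", ["nj", "bme_nni"])
@pytest.mark.parametrize("topology", ["ab|cd", "ac|bd", "ad|bc"])
def test_four_taxon_recovery_matches_ls_oracle(method, topology):
    d = four_taxon_matrix(topology)
    assert ls_best_topology(d) == topology
    t = infer_tree(d, method)
    cherry = frozenset(topology.split("|")[1])  # block without reference 'a'
    assert bipartitions(t) == {cherry}


@pytest.mark.parametrize("method", ["nj", "bme_nni"])
def test_additive_eight_taxon_exact_recovery(method):
    ref = random_tree(8, 0.3, seed=77)
    d = additive_distance_matrix(ref)
    t = infer_tree(d, method)
    assert robinson_foulds(t, ref) == 0


def test_bme_attains_true_length_on_additive_matrix():
    ref = random_tree(8, 0.3, seed=42)
    d = additive_distance_matrix(ref)
    t = infer_tree(d, "bme_nni")
    true_length = sum(e.length for e in ref.edges() if e.length)
    assert bme_length(t, d) == pytest.approx(true_length, rel=1e-9)
    inferred_length = sum(e.length for e in t.edges() if e.length)
    assert inferred_length == pytest.approx(true_length, rel=1e-6)


def test_nni_never_increases_balanced_criterion(rng):
    # noisy matrix: the refined tree is never worse than the NJ start
    ref = random_tree(10, 0.2, seed=5)
    d = additive_distance_matrix(ref)
    noisy = d.values + rng.uniform(0, 0.15, d.values.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    dm = DistanceMatrix(d.ids, noisy)
    nj_tree = infer_tree(dm, "nj")
    bme_tree = infer_tree(dm, "bme_nni")
    assert bme_length(bme_tree, dm) <= bme_length(nj_tree, dm) + 1e-9


def test_taxon_order_invariance():
    ref = random_tree(9, 0.25, seed=9)
    d = additive_distance_matrix(ref)
    perm = np.random.default_rng(0).permutation(d.n)
    d2 = DistanceMatrix([d.ids[i] for i in perm], d.values[np.ix_(perm, perm)])
    t1 = infer_tree(d, "bme_nni")
    t2 = infer_tree(d2, "bme_nni")
    assert robinson_foulds(t1, t2) == 0


def test_inferred_trees_are_binary(sim_family):
    from bitphylo.pipeline import distances_for
    seqs, _ = sim_family
    t = infer_tree(distances_for(seqs), "bme_nni")
    assert leaf_labels(t) == set(seqs.ids)
    assert len(bipartitions(t)) == len(seqs) - 3  # strictly bifurcating
    for e in t.preorder_edge_iter():
        assert e.length is None or e.length >= 0


def test_zero_distance_pair_forms_zero_length_cherry():
    ref = random_tree(6, 0.3, seed=3)
    d = additive_distance_matrix(ref)
    v = d.values.copy()
    ids = d.ids + ["twin"]
    n = len(ids)
    w = np.zeros((n, n))
    w[:n - 1, :n - 1] = v
    w[n - 1, :n - 1] = v[0, :]
    w[:n - 1, n - 1] = v[0, :]
    t = infer_tree(DistanceMatrix(ids, w), "bme_nni")
    assert frozenset({d.ids[0], "twin"}) in bipartitions(t) or \
        frozenset(set(ids) - {d.ids[0], "twin"}) in bipartitions(t)


def test_too_few_taxa_and_bad_distances_rejected():
    with pytest.raises(TreeError, match=">= 4 taxa"):
        infer_tree(DistanceMatrix(list("abc"), np.zeros((3, 3))))


def test_newick_roundtrip(tmp_path):
    for nwk in ["((a:1,b:1):1,(c:1,d:1):1);",
                "(a:0.5,b:0.25,(c:1,d:1,e:2):0.125);"]:
        t = read_newick(nwk, is_path=False)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert robinson_foulds(t, back) == 0
        assert leaf_labels(back) == leaf_labels(t)
        lengths = sorted(e.length for e in back.preorder_edge_iter()
                         if e.length is not None)
        expected = sorted(e.length for e in t.preorder_edge_iter()
                          if e.length is not None)
        assert lengths == pytest.approx(expected)


def test_malformed_newick_rejected():
    with pytest.raises(TreeError, match="malformed"):
        read_newick("((a,b),(c,d);", is_path=False)
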