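import dendropy
import numpy as np
import pytest

from bitphylo.consensus import (ConsensusError, bipartitions, compare_trees,
                                fit_theta_curve, majority_consensus,
                                robinson_foulds)
from bitphylo.simulate import random_tree
from bitphylo.trees import as_newick, read_newick


def t(nwk):
    return read_newick(nwk, is_path=False)


def test_bipartition_counts():
    binary8 = random_tree(8, 0.1, seed=0)
    assert len(bipartitions(binary8)) == 5  # n - 3
    star = t("(a,b,c,d,e);")
    assert bipartitions(star) == set()
    quartet = t("((a,b),(c,d));")
    assert bipartitions(quartet) == {frozenset({"c", "d"})}


def test_consensus_of_identical_trees_is_that_tree():
    trees = [t("((a:1,b:1):1,(c:1,d:1):1,e:1);") for _ in range(10)]
    cons = majority_consensus(trees)
    assert robinson_foulds(cons, trees[0]) == 0


def test_strict_majority_retention():
    with_split = t("((a,b),(c,d),e);")     # split {a,b} (and {c,d})
    without = t("((a,c),(b,d),e);")
    # 51 of 100 -> kept
    cons = majority_consensus([with_split] * 51 + [without] * 49)
    assert bipartitions(cons) == bipartitions(with_split)
    # 50 of 100 -> dropped entirely (ties excluded on both sides)
    cons50 = majority_consensus([with_split] * 50 + [without] * 50)
    assert bipartitions(cons50) == set()


def test_incompatible_half_splits_yield_polytomy():
    a = t("((a,b),(c,d),e);")
    b = t("((a,c),(b,d),e);")
    cons = majority_consensus([a, b])
    assert bipartitions(cons) == set()
    assert len(list(cons.leaf_node_iter())) == 5


def test_consensus_leafset_mismatch_rejected():
    with pytest.raises(ConsensusError, match="mismatch"):
        majority_consensus([t("((a,b),(c,d));"), t("((a,b),(c,e));")])


def test_compare_identical_and_star_trees():
    ref = random_tree(10, 0.1, seed=1)
    same = compare_trees(ref, ref)
    assert (same.tp, same.fp, same.fn, same.rf) == (7, 0, 0, 0)
    assert same.precision == same.recall == 1.0
    star = t("(" + ",".join(f"t{i}" for i in range(10)) + ");")
    c = compare_trees(star, ref)
    assert (c.tp, c.fp, c.fn) == (0, 0, 7)
    assert c.recall == 0.0
    assert c.precision == 1.0 and not c.precision_defined


def test_compare_matches_dendropy_oracle():
    # independent route: dendropy's bipartition machinery on a shared namespace
    from dendropy.calculate import treecompare
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = int(rng.integers(5, 13))
        t1 = random_tree(n, 0.1, seed=int(rng.integers(2 ** 31)))
        t2 = random_tree(n, 0.1, seed=int(rng.integers(2 ** 31)))
        cmp_ = compare_trees(t1, t2)
        ns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=as_newick(t1), schema="newick",
                               taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=as_newick(t2), schema="newick",
                               taxon_namespace=ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        fp, fn = treecompare.false_positives_and_negatives(d2, d1)
        assert (cmp_.fp, cmp_.fn) == (fp, fn)
        assert cmp_.rf == cmp_.fp + cmp_.fn


def test_rf_metric_properties():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n = int(rng.integers(5, 11))
        trees = [random_tree(n, 0.1, seed=int(rng.integers(2 ** 31)))
                 for _ in range(3)]
        a, b, c = trees
        assert robinson_foulds(a, a) == 0
        assert robinson_foulds(a, b) == robinson_foulds(b, a)
        assert robinson_foulds(a, c) <= \
            robinson_foulds(a, b) + robinson_foulds(b, c)
        assert robinson_foulds(a, b) <= 2 * (n - 3)


def test_consensus_bipartitions_pairwise_compatible():
    rng = np.random.default_rng(11)
    trees = [random_tree(9, 0.1, seed=int(rng.integers(2 ** 31)))
             for _ in range(9)]
    cons = majority_consensus(trees)
    splits = list(bipartitions(cons))
    labels = {lf.taxon.label for lf in cons.leaf_node_iter()}
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            a, b = set(splits[i]), set(splits[j])
            a2, b2 = labels - a, labels - b
            assert (not (a & b) or not (a & b2)
                    or not (a2 & b) or not (a2 & b2))


def test_majority_consensus_matches_dendropy():
    rng = np.random.default_rng(13)
    base = random_tree(8, 0.1, seed=3)
    trees = [base] * 6 + [random_tree(8, 0.1, seed=int(rng.integers(2 ** 31)))
                          for _ in range(4)]
    mine = majority_consensus(trees)
    ns = dendropy.TaxonNamespace()
    dlist = dendropy.TreeList(
        [dendropy.Tree.get(data=as_newick(x), schema="newick",
                           taxon_namespace=ns) for x in trees])
    theirs = dlist.consensus(min_freq=0.5)
    assert bipartitions(mine) == bipartitions(theirs)


def test_calibration_parabola_vertex():
    thetas = np.linspace(0, 5, 11)
    vertex = 2.2
    rf = 3.0 + (thetas - vertex) ** 2
    theta_opt, _ = fit_theta_curve(thetas, rf, degree=4)
    assert theta_opt == pytest.approx(vertex, abs=1e-3)


def test_calibration_flat_curve_returns_lower_bound():
    thetas = np.linspace(0.5, 4, 8)
    with pytest.warns(UserWarning, match="flat"):
        theta_opt, _ = fit_theta_curve(thetas, np.full(8, 7.0), degree=2)
    assert theta_opt == 0.5


def test_calibration_grid_too_small():
    with pytest.raises(ConsensusError, match="degree"):
        fit_theta_curve(np.array([0, 1, 2.0]), np.array([1, 2, 3.0]), degree=4)
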