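"""Quartet scores, species-tree search and consensus splits."""

from itertools import combinations

import numpy as np
import pytest

from phylodisc.simnet import SpeciesNetwork, simulate_gene_trees
from phylodisc.sptree import (consensus_splits, infer_species_tree,
                              quartet_scores)
from phylodisc.trees import (GeneTree, TreeArrays, build_index,
                             canonical_topology, tree_from_newick)

SIX_TAXON = "(((A:0.5,B:0.5):0.5,(C:0.7,D:0.7):0.3):1.0,(E:1.5,F:1.5):0.5);"


@pytest.fixture(scope="module")
def six_taxon_trees():
    net = SpeciesNetwork(newick=SIX_TAXON)
    return simulate_gene_trees(net, 500, seed=19)


def test_concordant_input_gives_q1_one():
    sp = tree_from_newick(SIX_TAXON)
    trees = [tree_from_newick(SIX_TAXON) for _ in range(10)]
    for q in quartet_scores(sp, trees):
        assert q.q1 == 1.0
        assert q.q2 == q.q3 == 0.0


def test_scores_normalised_on_every_branch(six_taxon_trees):
    sp = tree_from_newick(SIX_TAXON)
    for q in quartet_scores(sp, six_taxon_trees):
        assert q.q1 + q.q2 + q.q3 == pytest.approx(1.0, abs=1e-9)


def test_scores_equal_exhaustive_enumeration(six_taxon_trees):
    """q values must match a brute-force oracle that loops over every
    quartet and every gene tree independently of the implementation."""
    sp = tree_from_newick(SIX_TAXON)
    taxa = sorted("ABCDEF")
    index = build_index(taxa)
    got = {q.branch_id: (q.q1, q.q2, q.q3)
           for q in quartet_scores(sp, six_taxon_trees)}

    def clades_of(branch_id):
        # reconstruct the four clades around the branch by brute force
        inside = set(branch_id.split(","))
        sp_t = tree_from_newick(SIX_TAXON)
        for node in sp_t.tree.preorder_node_iter():
            below = {l.taxon.label for l in node.leaf_iter()}
            if below == inside:
                ch = node.child_nodes()
                A = {l.taxon.label for l in ch[0].leaf_iter()}
                B = {l.taxon.label for l in ch[1].leaf_iter()}
                parent = node.parent_node
                sibs = [c for c in parent.child_nodes() if c is not node]
                if parent.parent_node is not None:
                    C = set()
                    for s in sibs:
                        C |= {l.taxon.label for l in s.leaf_iter()}
                    D = set(taxa) - inside - C
                else:
                    gch = sibs[0].child_nodes()
                    C = {l.taxon.label for l in gch[0].leaf_iter()}
                    D = {l.taxon.label for l in gch[1].leaf_iter()}
                return A, B, C, D
        raise AssertionError(branch_id)

    for branch_id, qvals in got.items():
        A, B, C, D = clades_of(branch_id)
        tally = np.zeros(3)
        for a in A:
            for b in B:
                for c in C:
                    for d in D:
                        for gt in six_taxon_trees:
                            ta = TreeArrays(gt, index)
                            s = ta.quartet_split(
                                1 << index[a], 1 << index[b],
                                1 << index[c], 1 << index[d])
                            if s is not None:
                                tally[s] += 1
        expected = tally / tally.sum()
        assert qvals == pytest.approx(tuple(expected), abs=1e-12)


def test_internal_branch_alternatives_match_msc_closed_form():
    """Branch of length tau=1 on a caterpillar tree: q2 and q3 each
    ~ (1/3) e^(-1).

    The closed form requires the deeper branches to be long enough that
    lineages escaping the focal branch resolve before further mixing (a
    caterpillar with long ancestral edges); a branch flanked by a sister
    cherry instead multiplies in that pair's own failure probability.
    """
    cat = ("(((((A:1.0,B:1.0):1.0,C:2.0):10.0,D:12.0):1.0,E:13.0):1.0,"
           "F:14.0);")
    net = SpeciesNetwork(newick=cat)
    trees = simulate_gene_trees(net, 10_000, seed=23)
    sp = tree_from_newick(cat)
    scores = {q.branch_id: q for q in quartet_scores(sp, trees)}
    q = scores["A,B"]  # internal branch above the (A,B) cherry, tau = 1
    expected = (1 / 3) * np.exp(-1)
    assert q.q2 == pytest.approx(expected, abs=0.02)
    assert q.q3 == pytest.approx(expected, abs=0.02)


def test_species_tree_recovery_and_exhaustive_maximum(six_taxon_trees):
    est, supports = infer_species_tree(six_taxon_trees, outgroup="F")
    assert canonical_topology(est, outgroup="F") == \
        canonical_topology(tree_from_newick(SIX_TAXON), outgroup="F")
    assert supports  # quartet supports attached


def test_refuses_fewer_than_three_gene_trees():
    trees = [tree_from_newick(SIX_TAXON)] * 2
    with pytest.raises(ValueError):
        infer_species_tree(trees)


def test_hybrid_simulation_top_two_topologies_differ_in_conflict_branch():
    from phylodisc.simnet import HybridEdge
    from phylodisc.winphylo import tabulate_topologies
    nwk = ("((((H1:0.5,H2:0.5):0.5,(P1a:0.5,P1b:0.5):0.5):0.3,"
           "(P2a:0.5,P2b:0.5):0.8):3.7,OUT:5.0);")
    net = SpeciesNetwork(newick=nwk, outgroup="OUT",
                         hybrid=HybridEdge(recipient=("H1", "H2"),
                                           donor=("P2a", "P2b"),
                                           time=1.0, gamma=0.5))
    trees = simulate_gene_trees(net, 2000, seed=29)
    tab = tabulate_topologies(trees, outgroup="OUT")
    top1, top2 = tab.top(2)
    # the two most common topologies attach the hybrid clade to the two
    # different parental clades and agree everywhere else
    assert {"((((H1,H2),(P1a,P1b)),(P2a,P2b)),OUT);",
            "((((H1,H2),(P2a,P2b)),(P1a,P1b)),OUT);"} == {top1, top2}


class TestConsensusSplits:
    def _trees(self, fracs):
        """Trees exhibiting split AB with given frequency etc."""
        out = []
        for nwk, n in fracs:
            out += [tree_from_newick(nwk) for _ in range(n)]
        return out

    def test_split_below_threshold_excluded(self):
        trees = self._trees([("((A,B),(C,(D,E)));", 29),
                             ("((A,C),(B,(D,E)));", 71)])
        ss = consensus_splits(trees, 0.30)
        assert frozenset("AB") not in ss.splits

    def test_universal_split_always_included(self):
        trees = self._trees([("((A,B),(C,(D,E)));", 10)])
        ss = consensus_splits(trees, 1.0)
        assert frozenset("DE") in ss.splits or frozenset("ABC") in ss.splits

    def test_incompatible_splits_both_reported(self):
        trees = self._trees([("((A,B),(C,(D,E)));", 40),
                             ("((A,C),(B,(D,E)));", 35),
                             ("((A,D),(C,(B,E)));", 25)])
        ss = consensus_splits(trees, 0.30)
        sides = set(ss.splits)
        # AB (40%) and AC (35%) are incompatible yet both present
        def has(pair):
            p = frozenset(pair)
            full = frozenset("ABCDE")
            return p in sides or (full - p) in sides
        assert has("AB") and has("AC")

    def test_lowering_threshold_never_removes_splits(self, six_taxon_trees):
        hi = consensus_splits(six_taxon_trees, 0.30).splits
        lo = consensus_splits(six_taxon_trees, 0.10).splits
        assert set(hi) <= set(lo)
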