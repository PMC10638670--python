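"""Quartet-support species-tree estimation and consensus-split networks.

The species tree is the topology maximising summed gene-tree quartet
concordance (the criterion ASTRAL optimises), found by exhaustive search
over all unrooted topologies for up to 8 taxa and by greedy taxon
insertion with NNI refinement beyond.  Per-branch quartet scores q1/q2/q3
give the proportion of gene-tree quartets around each internal branch
supporting the species-tree arrangement and the two alternatives.

Branch "support" is a multinomial tail heuristic (probability that the
observed q1 excess over the best alternative would arise by chance), a
deliberately simple stand-in for ASTRAL's local posterior probability; it
is not numerically comparable to ASTRAL PPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .trees import GeneTree, TreeArrays, build_index, root_with_outgroup, \
    tree_from_newick

__all__ = [
    "QuartetSupport",
    "SplitSet",
    "quartet_scores",
    "infer_species_tree",
    "consensus_splits",
]


@dataclass
class QuartetSupport:
    """Quartet score triple for one internal species-tree branch."""

    branch_id: str                    # canonical label of the child clade
    clades: tuple[frozenset, ...]     # the four branch-adjacent clades
    q1: float
    q2: float
    q3: float
    n_quartets: int                   # quartet x gene-tree observations
    support: float                    # tail-probability stand-in, see module doc

    def __post_init__(self):
        s = self.q1 + self.q2 + self.q3
        if self.n_quartets and abs(s - 1.0) > 1e-9:
            raise ValueError("quartet scores must sum to 1")


@dataclass
class SplitSet:
    """Bipartitions with gene-tree support frequency (network semantics:
    mutually incompatible splits are all retained)."""

    taxa: list[str]
    splits: dict[frozenset, float]
    threshold: float


# ---------------------------------------------------------------------------
# quartet tallies


def _gene_tree_digests(gene_trees: Sequence[GeneTree], index):
    return [TreeArrays(gt, index) for gt in gene_trees]


def _quartet_counts(digests, index) -> dict[tuple[int, int, int, int], np.ndarray]:
    """counts[(a,b,c,d) bit tuple, a<b<c<d] -> tally of ab|cd, ac|bd, ad|bc."""
    bits = sorted(1 << i for i in index.values())
    table: dict[tuple[int, int, int, int], np.ndarray] = {}
    for quart in combinations(bits, 4):
        tally = np.zeros(3, dtype=np.int64)
        a, b, c, d = quart
        for ta in digests:
            s = ta.quartet_split(a, b, c, d)
            if s is not None:
                tally[s] += 1
        table[quart] = tally
    return table


def _split_of_quartet(masks: Iterable[int], a, b, c, d) -> int | None:
    quart = a | b | c | d
    for m in masks:
        inter = m & quart
        if bin(inter).count("1") == 2:
            if inter in (a | b, c | d):
                return 0
            if inter in (a | c, b | d):
                return 1
            return 2
        inter = ~m & quart  # check complement side too
        if bin(inter).count("1") == 2:
            if inter in (a | b, c | d):
                return 0
            if inter in (a | c, b | d):
                return 1
            return 2
    return None


# ---------------------------------------------------------------------------
# quartet scores around species-tree branches


def _branch_clades(sp: GeneTree):
    """Yield (branch_id, [A, B, C, D]) for internal branches with four
    non-empty adjacent clades, as frozensets of species names."""
    tree = sp.tree
    all_leaves = frozenset(sp.species_of(l) for l in sp.leaf_labels())
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([sp.species_of(node.taxon.label)])
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= leafsets[id(ch)]
            leafsets[id(node)] = s
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is root:
            continue
        ch = node.child_nodes()
        if len(ch) != 2:
            continue
        A, B = leafsets[id(ch[0])], leafsets[id(ch[1])]
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        if parent is not root:
            C = frozenset()
            for s in sibs:
                C |= leafsets[id(s)]
            D = all_leaves - leafsets[id(node)] - C
        else:
            if len(sibs) != 1 or sibs[0].is_leaf():
                continue
            gch = sibs[0].child_nodes()
            if len(gch) != 2:
                continue
            C, D = leafsets[id(gch[0])], leafsets[id(gch[1])]
        if min(len(A), len(B), len(C), len(D)) == 0:
            continue
        branch_id = ",".join(sorted(leafsets[id(node)]))
        yield branch_id, (A, B, C, D)


def quartet_scores(species_tree: GeneTree, gene_trees: Sequence[GeneTree],
                   max_quartets_per_branch: int = 20000,
                   seed: int = 0) -> list[QuartetSupport]:
    """q1/q2/q3 per internal branch by exact quartet enumeration.

    All quartets with one leaf from each of the four branch-adjacent
    clades are classified in every gene tree; above
    ``max_quartets_per_branch`` quartets a seeded uniform sample is used.
    """
    species = sorted({species_tree.species_of(l)
                      for l in species_tree.leaf_labels()})
    index = build_index(species)
    digests = _gene_tree_digests(gene_trees, index)
    rng = np.random.default_rng(seed)
    out = []
    for branch_id, (A, B, C, D) in _branch_clades(species_tree):
        quartets = [(a, b, c, d) for a in sorted(A) for b in sorted(B)
                    for c in sorted(C) for d in sorted(D)]
        if len(quartets) > max_quartets_per_branch:
            pick = rng.choice(len(quartets), size=max_quartets_per_branch,
                              replace=False)
            quartets = [quartets[i] for i in sorted(pick)]
        tally = np.zeros(3, dtype=np.int64)
        for a, b, c, d in quartets:
            ba, bb, bc, bd = (1 << index[a], 1 << index[b],
                              1 << index[c], 1 << index[d])
            for ta in digests:
                s = ta.quartet_split(ba, bb, bc, bd)
                if s is not None:
                    tally[s] += 1
        n = int(tally.sum())
        if n == 0:
            q = (0.0, 0.0, 0.0)
            support = 0.0
        else:
            q = tuple(tally / n)
            # tail heuristic: z of q1's excess over the better alternative
            n1, nalt = tally[0], max(tally[1], tally[2])
            denom = np.sqrt(max(n1 + nalt, 1))
            support = float(norm.cdf((n1 - nalt) / denom))
        out.append(QuartetSupport(branch_id=branch_id,
                                  clades=(A, B, C, D),
                                  q1=float(q[0]), q2=float(q[1]),
                                  q3=float(q[2]), n_quartets=n,
                                  support=support))
    return out


# ---------------------------------------------------------------------------
# species-tree search


def _enumerate_topologies(taxa: Sequence[str]):
    """All unrooted binary topologies, as nested tuples rooted at a handle
    leaf ``taxa[0]`` (the handle leaf itself is implicit)."""
    rest = list(taxa[1:])

    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            l, r = tree
            for sub in insert_everywhere(l, leaf):
                yield (sub, r)
            for sub in insert_everywhere(r, leaf):
                yield (l, sub)

    trees = [rest[0] if len(rest) == 1 else (rest[0], rest[1])]
    for leaf in rest[2:]:
        trees = [t2 for t in trees for t2 in insert_everywhere(t, leaf)]
    return trees


def _topology_masks(tree, index) -> list[int]:
    masks = []

    def walk(node) -> int:
        if isinstance(node, str):
            return 1 << index[node]
        m = walk(node[0]) | walk(node[1])
        masks.append(m)
        return m

    walk(tree)
    return masks


def _topology_newick(tree, handle: str) -> str:
    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(sorted([render(node[0]), render(node[1])])) + ")"
    return f"({handle},{render(tree)});"


def _score_topology(masks, counts_table, index) -> int:
    score = 0
    for quart, tally in counts_table.items():
        s = _split_of_quartet(masks, *quart)
        if s is not None:
            score += int(tally[s])
        else:
            pass
    return score


def infer_species_tree(gene_trees: Sequence[GeneTree],
                       outgroup: str | None = None,
                       seed: int = 0
                       ) -> tuple[GeneTree, list[QuartetSupport]]:
    """Maximum-quartet-support species tree.

    Exhaustive over all unrooted topologies for <=8 taxa; greedy stepwise
    insertion with NNI refinement beyond.  Ties break lexicographically on
    the canonical topology string, so the result is deterministic.
    """
    if len(gene_trees) < 3:
        raise ValueError("need at least 3 gene trees")
    species = sorted({gt.species_of(l) for gt in gene_trees[:1]
                      for l in gt.leaf_labels()})
    if len(species) < 4:
        raise ValueError("need >= 4 taxa")
    index = build_index(species)
    digests = _gene_tree_digests(gene_trees, index)
    counts_table = _quartet_counts(digests, index)

    if len(species) <= 8:
        candidates = _enumerate_topologies(species)
        best, best_score, best_key = None, -1, None
        for t in candidates:
            masks = _topology_masks(t, index)
            sc = _score_topology(masks, counts_table, index)
            key = _topology_newick(t, species[0])
            if sc > best_score or (sc == best_score and key < best_key):
                best, best_score, best_key = t, sc, key
        newick = _topology_newick(best, species[0])
    else:
        newick = _greedy_search(species, counts_table, index)

    gt = tree_from_newick(newick)
    for e in gt.tree.preorder_edge_iter():
        e.length = None
    if outgroup is not None and outgroup in species:
        gt = root_with_outgroup(gt, outgroup)
    supports = quartet_scores(gt, gene_trees, seed=seed)
    return gt, supports


def _nni_neighbours(tree):
    """Yield NNI rearrangements of a handle-rooted nested-tuple tree."""
    def rearr(node):
        if isinstance(node, str):
            return
        l, r = node
        if isinstance(l, tuple):
            a, b = l
            yield ((a, r), b)
            yield ((b, r), a)
        if isinstance(r, tuple):
            a, b = r
            yield (b, (a, l))
            yield (a, (b, l))
        for sub in rearr(l):
            yield (sub, r)
        for sub in rearr(r):
            yield (l, sub)
    yield from rearr(tree)


def _greedy_search(species, counts_table, index) -> str:
    def insert_everywhere(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            l, r = tree
            for sub in insert_everywhere(l, leaf):
                yield (sub, r)
            for sub in insert_everywhere(r, leaf):
                yield (l, sub)

    def score(t):
        return _score_topology(_topology_masks(t, index), counts_table, index)

    def pick(cands):
        best, bs, bk = None, -1, None
        for t in cands:
            sc = score(t)
            key = _topology_newick(t, species[0])
            if sc > bs or (sc == bs and key < bk):
                best, bs, bk = t, sc, key
        return best, bs

    tree = (species[1], species[2])
    for leaf in species[3:]:
        tree, _ = pick(insert_everywhere(tree, leaf))
    # NNI hill climb
    cur, cur_score = tree, score(tree)
    improved = True
    while improved:
        improved = False
        best, bs = pick(_nni_neighbours(cur))
        if best is not None and bs > cur_score:
            cur, cur_score = best, bs
            improved = True
    return _topology_newick(cur, species[0])


# ---------------------------------------------------------------------------
# consensus splits


def consensus_splits(gene_trees: Sequence[GeneTree],
                     threshold: float) -> SplitSet:
    """All bipartitions with gene-tree frequency >= threshold.

    Incompatible splits are retained (consensus-network semantics), so
    lowering the threshold can only add splits, never remove them.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    species = sorted({gene_trees[0].species_of(l)
                      for l in gene_trees[0].leaf_labels()})
    index = build_index(species)
    counts: dict[int, int] = {}
    n = 0
    for gt in gene_trees:
        ta = TreeArrays(gt, index)
        n += 1
        for m in ta.bipartitions():
            counts[m] = counts.get(m, 0) + 1
    splits: dict[frozenset, float] = {}
    for m, c in counts.items():
        freq = c / n
        if freq >= threshold:
            side = frozenset(sp for sp, i in index.items() if m >> i & 1)
            splits[side] = freq
    return SplitSet(taxa=species, splits=splits, threshold=threshold)
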