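"""Gene-tree container and topology utilities.

Trees are held as :class:`dendropy.Tree` objects wrapped in a light
:class:`GeneTree` record that carries the leaf-to-species map, the unit of
the branch lengths (coalescent units vs substitutions per site) and the
locus/window of origin.  The hot operations used by the discordance
statistics -- triplet restriction, quartet splits, bipartition tabulation --
work on integer leaf-set bitmasks computed in a single post-order pass, so
they stay cheap over tens of thousands of loci.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from typing import Iterable, Sequence

import dendropy

__all__ = [
    "GeneTree",
    "TreeArrays",
    "canonical_topology",
    "read_newick_trees",
    "write_newick_trees",
    "root_with_outgroup",
    "tree_from_newick",
]

COALESCENT = "coalescent"
SUBS_PER_SITE = "subs_per_site"


@dataclass
class GeneTree:
    """A rooted gene tree with species-mapped leaves.

    Parameters
    ----------
    tree:
        The underlying dendropy tree (rooted; binary except where an
        inference step produced a polytomy).
    length_unit:
        ``"coalescent"`` (units of 2N generations) or ``"subs_per_site"``.
    locus_id:
        Identifier of the window/locus of origin, or ``None``.
    species_map:
        Leaf label -> species name.  Defaults to the identity map.
    meta:
        Free-form provenance (e.g. which parental path a locus took
        through a hybrid edge).
    """

    tree: dendropy.Tree
    length_unit: str = COALESCENT
    locus_id: int | str | None = None
    species_map: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def species_of(self, leaf_label: str) -> str:
        return self.species_map.get(leaf_label, leaf_label)

    def newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def copy(self) -> "GeneTree":
        return GeneTree(
            tree=self.tree.clone(depth=1),
            length_unit=self.length_unit,
            locus_id=self.locus_id,
            species_map=dict(self.species_map),
            meta=dict(self.meta),
        )


def tree_from_newick(newick: str, length_unit: str = COALESCENT,
                     locus_id=None) -> GeneTree:
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    return GeneTree(tree=t, length_unit=length_unit, locus_id=locus_id)


def read_newick_trees(path, length_unit: str = SUBS_PER_SITE) -> list[GeneTree]:
    """Read a one-Newick-per-line file; ``[...]`` comments are tolerated.

    Malformed lines raise :class:`ValueError` carrying the line number.
    """
    out: list[GeneTree] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                t = dendropy.Tree.get(data=line, schema="newick",
                                      preserve_underscores=True)
            except Exception as exc:  # dendropy raises assorted error types
                raise ValueError(f"malformed Newick at line {i}: {exc}") from exc
            out.append(GeneTree(tree=t, length_unit=length_unit, locus_id=i - 1))
    return out


def write_newick_trees(trees: Iterable[GeneTree], path) -> None:
    with open(path, "w") as fh:
        for gt in trees:
            comment = "" if gt.locus_id is None else f"[&locus={gt.locus_id}]"
            fh.write(gt.newick().rstrip(";") + ";" + comment + "\n")


def root_with_outgroup(gt: GeneTree, outgroup: str) -> GeneTree:
    """Return a copy rooted on the edge subtending the outgroup leaf.

    ``outgroup`` may name a species: every leaf mapping to that species
    must form a clade on one side of an edge; rooting happens there.
    """
    gt = gt.copy()
    tree = gt.tree
    og_leaves = [lf for lf in tree.leaf_node_iter()
                 if gt.species_of(lf.taxon.label) == outgroup]
    if not og_leaves:
        raise ValueError(f"outgroup {outgroup!r} not among leaves")
    if len(og_leaves) == 1:
        node = og_leaves[0]
    else:
        node = tree.mrca(taxa=[lf.taxon for lf in og_leaves])
    edge = node.edge
    if edge.tail_node is None:
        return gt  # already rooted here
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=False)
    return gt


# ---------------------------------------------------------------------------
# bitmask machinery


class TreeArrays:
    """Bitmask/root-distance digest of one rooted gene tree.

    ``index`` maps unit names (species by default) to bit positions; leaves
    whose unit is not in the index are ignored, so gene trees with extra
    taxa restrict cleanly.
    """

    def __init__(self, gt: GeneTree, index: dict[str, int],
                 by_species: bool = True):
        self.index = index
        masks: list[int] = []
        lengths: list[float] = []
        rdists: list[float] = []
        node_mask: dict[int, int] = {}
        node_rdist: dict[int, float] = {}
        for node in gt.tree.preorder_node_iter():
            parent = node.parent_node
            d = (node_rdist[id(parent)] if parent is not None else 0.0) + \
                (node.edge.length or 0.0)
            node_rdist[id(node)] = d
        for node in gt.tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                unit = gt.species_of(label) if by_species else label
                m = 1 << index[unit] if unit in index else 0
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= node_mask[id(ch)]
            node_mask[id(node)] = m
            if m:
                masks.append(m)
                lengths.append(node.edge.length or 0.0)
                rdists.append(node_rdist[id(node)])
        self.masks = masks
        self.lengths = lengths
        self.rdists = rdists
        self.full = (1 << len(index)) - 1
        # present = union of leaf bits actually found
        present = 0
        for m, l in zip(masks, lengths):
            if bin(m).count("1") == 1:
                present |= m
        self.present = present

    def _mrca(self, mask: int) -> tuple[int, float]:
        """(clade size, root distance) of the MRCA of the units in
        ``mask``; clade size is in tree leaves overlapping the index."""
        best_pop, best = None, 0.0
        for m, d in zip(self.masks, self.rdists):
            if m & mask == mask:
                p = bin(m).count("1")
                if best_pop is None or p < best_pop:
                    best, best_pop = d, p
        if best_pop is None:
            best_pop = bin(self.present).count("1")
        return best_pop, best

    def mrca_rdist(self, mask: int) -> float:
        """Root-distance of the MRCA of the units in ``mask``."""
        return self._mrca(mask)[1]

    def quartet_split(self, a: int, b: int, c: int, d: int) -> int | None:
        """Resolved split of the quartet with unit bits ``a..d``.

        Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, ``None`` if the
        quartet is unresolved (star) in this tree.
        """
        quart = a | b | c | d
        for m in self.masks:
            inter = m & quart
            pop = bin(inter).count("1")
            if pop == 2:
                if inter == a | b or inter == c | d:
                    return 0
                if inter == a | c or inter == b | d:
                    return 1
                if inter == a | d or inter == b | c:
                    return 2
        return None

    def triplet(self, a: int, b: int, c: int):
        """Topology class and internal branch length of a rooted triplet.

        Returns ``(cherry_pair_bits, internal_length)`` where
        ``cherry_pair_bits`` is the OR of the two cherry bits; a polytomy
        yields the lexicographically smallest pair and length 0.
        """
        trip = a | b | c
        _, d_all = self._mrca(trip)
        pairs = sorted([a | b, a | c, b | c])
        stats = [self._mrca(p) for p in pairs]  # (clade size, depth)
        # cherry = pair with the smallest MRCA clade (topological), with
        # depth as a secondary criterion so length-free trees work too
        key = [(pop, -d) for pop, d in stats]
        best = min(key)
        winners = [p for p, k in zip(pairs, key) if k == best]
        cherry = winners[0]
        depth = stats[key.index(best)][1]
        if len(winners) > 1 or depth <= d_all:
            return cherry, 0.0
        return cherry, max(depth - d_all, 0.0)

    def bipartitions(self, restrict: int | None = None) -> dict[int, None]:
        """Non-trivial bipartitions as canonical masks.

        Each split is normalised to the side *not* containing bit 0 of the
        (optionally restricted) taxon set.
        """
        full = self.present if restrict is None else (self.present & restrict)
        nbits = bin(full).count("1")
        out: dict[int, None] = {}
        low = full & -full  # lowest set bit as reference side
        for m in self.masks:
            s = m & full
            pop = bin(s).count("1")
            if pop < 2 or pop > nbits - 2:
                continue
            if s & low:
                s = full & ~s
            out[s] = None
        return out


def build_index(units: Sequence[str]) -> dict[str, int]:
    return {u: i for i, u in enumerate(sorted(units))}


# ---------------------------------------------------------------------------
# canonical topology strings


def canonical_topology(gt: GeneTree, outgroup: str | None = None,
                       by_species: bool = True) -> str:
    """Branch-length-free canonical Newick of a tree's topology.

    The tree is (re)rooted on the outgroup when one is given; children are
    recursively sorted by their smallest leaf label so that label order and
    branch lengths never affect the string.
    """
    if outgroup is not None:
        gt = root_with_outgroup(gt, outgroup)

    def render(node) -> tuple[str, str]:
        if node.is_leaf():
            lab = gt.species_of(node.taxon.label) if by_species \
                else node.taxon.label
            return lab, lab
        parts = sorted(render(ch) for ch in node.child_nodes())
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return render(gt.tree.seed_node)[1] + ";"
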