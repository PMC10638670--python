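"""Synthetic data under a multispecies coalescent on a species network.

The generator emulates the statistical structure of a rapid radiation with
high incomplete lineage sorting (ILS) and at most one ancient hybridization
event: a rooted species tree with branch lengths in coalescent units
(2N generations), per-branch relative effective sizes, and an optional
hybrid edge with inheritance probability ``gamma``.  Hybridization follows
hybrid-speciation semantics: each locus independently follows either the
major parental tree or, with probability ``gamma``, the tree in which the
recipient clade attaches to the donor lineage.  Coalescence within each
branch is simulated with msprime; branch lengths of the returned gene
trees are in coalescent units.

Mutations are laid down under an infinite-sites model (no back mutation),
so site-pattern polarisation against the outgroup is exact, and loci are
tiled on a synthetic coordinate system with configurable inter-locus gaps
so that all the windowing machinery downstream is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import msprime
import numpy as np

from .trees import COALESCENT, GeneTree

__all__ = [
    "SpeciesNetwork",
    "HybridEdge",
    "GenotypeMatrix",
    "simulate_gene_trees",
    "simulate_genotypes",
    "simulate_admixed_panel",
]


class NetworkError(ValueError):
    """Structural problem with a species network."""


@dataclass
class HybridEdge:
    """One reticulation: the recipient clade's ancestral lineage jumps to
    the donor lineage at ``time`` (coalescent units above the leaves) with
    probability ``gamma`` per locus."""

    recipient: tuple[str, ...]  # leaf labels spanning the recipient clade
    donor: tuple[str, ...]      # leaf labels spanning the donor clade
    time: float
    gamma: float

    def __post_init__(self):
        self.recipient = tuple(self.recipient)
        self.donor = tuple(self.donor)
        if not 0.0 <= self.gamma <= 1.0:
            raise NetworkError(f"gamma must be in [0,1], got {self.gamma}")
        if self.time < 0:
            raise NetworkError("hybrid edge time must be >= 0")


@dataclass
class SpeciesNetwork:
    """Rooted species tree (coalescent-unit branch lengths, per-branch
    relative population sizes) plus at most one hybrid edge.

    Parameters
    ----------
    newick:
        Rooted, ultrametric species tree with branch lengths in units of
        2N generations.
    pop_sizes:
        Relative effective size of the branch above a node, keyed by leaf
        label or by a frozenset of the leaf labels of an internal clade.
        Branches not listed have relative size 1.  Ancestral sizes are a
        visible model choice, never a hidden constant.
    hybrid:
        Optional :class:`HybridEdge`.
    outgroup:
        Leaf that must attach basal to the in-group.
    """

    newick: str
    outgroup: str | None = None
    pop_sizes: dict = field(default_factory=dict)
    hybrid: HybridEdge | None = None

    def __post_init__(self):
        self._tree = dendropy.Tree.get(data=self.newick, schema="newick",
                                       preserve_underscores=True)
        self._validate()

    # -- structure -----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def _clade_node(self, tree: dendropy.Tree, labels: Sequence[str]):
        labels = set(labels)
        for node in tree.postorder_node_iter():
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if below == labels:
                return node
        raise NetworkError(f"no clade spans {sorted(labels)}")

    def _heights(self, tree: dendropy.Tree) -> dict[int, float]:
        """Node heights above the leaves; enforces ultrametricity."""
        h: dict[int, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                h[id(node)] = 0.0
                continue
            hs = [h[id(ch)] + (ch.edge.length or 0.0)
                  for ch in node.child_nodes()]
            if max(hs) - min(hs) > 1e-6 * max(1.0, max(hs)):
                raise NetworkError(
                    "species tree must be ultrametric in coalescent units")
            h[id(node)] = max(hs)
        return h

    def _validate(self):
        tree = self._tree
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise NetworkError("negative branch length")
        self._heights(tree)
        if self.outgroup is not None:
            if self.outgroup not in self.leaf_labels():
                raise NetworkError(f"outgroup {self.outgroup!r} not a leaf")
            root_children = self._tree.seed_node.child_nodes()
            basal = any(ch.is_leaf() and ch.taxon.label == self.outgroup
                        for ch in root_children)
            if not basal:
                raise NetworkError("outgroup must attach basal to the root")
        if self.hybrid is not None:
            self._minor_tree()  # raises if the reattachment is impossible

    # -- parental trees ------------------------------------------------

    def _major_tree(self) -> dendropy.Tree:
        return self._tree.clone(depth=1)

    def _minor_tree(self) -> dendropy.Tree:
        """Tree in which the recipient clade attaches to the donor edge."""
        hy = self.hybrid
        tree = self._tree.clone(depth=1)
        heights = self._heights(tree)
        rec = self._clade_node(tree, hy.recipient)
        rec_h = heights[id(rec)]
        if hy.time < rec_h:
            raise NetworkError("hybrid time predates the recipient clade")
        parent = rec.parent_node
        if parent is None:
            raise NetworkError("recipient clade cannot be the root")
        # detach recipient, suppress the unifurcation left behind
        parent.remove_child(rec)
        if len(parent.child_nodes()) == 1:
            only = parent.child_nodes()[0]
            gp = parent.parent_node
            if gp is None:
                tree.seed_node = only
                only.parent_node = None
                only.edge.length = None
            else:
                only.edge.length = (only.edge.length or 0.0) + \
                    (parent.edge.length or 0.0)
                gp.remove_child(parent)
                gp.add_child(only)
        heights = self._heights(tree)
        donor = self._clade_node(tree, hy.donor)
        donor_h = heights[id(donor)]
        dp = donor.parent_node
        top = heights[id(dp)] if dp is not None else float("inf")
        if not (donor_h <= hy.time <= top):
            raise NetworkError("hybrid time falls outside the donor edge")
        mid = dendropy.Node()
        if dp is not None:
            dp.remove_child(donor)
            dp.add_child(mid)
            mid.edge.length = top - hy.time
        else:
            tree.seed_node = mid
        mid.add_child(donor)
        donor.edge.length = hy.time - donor_h
        mid.add_child(rec)
        rec.edge.length = hy.time - rec_h
        return tree

    # -- msprime demography --------------------------------------------

    def _rel_size(self, node) -> float:
        if node.is_leaf():
            key = node.taxon.label
            if key in self.pop_sizes:
                return float(self.pop_sizes[key])
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        return float(self.pop_sizes.get(below, 1.0))

    def _demography(self, tree: dendropy.Tree):
        heights = self._heights(tree)
        demo = msprime.Demography()
        names: dict[int, str] = {}
        counter = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label
            else:
                name = f"anc{counter}"
                counter += 1
            names[id(node)] = name
            demo.add_population(name=name, initial_size=self._rel_size(node))
        splits = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            splits.append((heights[id(node)], node))
        splits.sort(key=lambda t: t[0])
        for time, node in splits:
            demo.add_population_split(
                time=max(time, 1e-12),
                derived=[names[id(ch)] for ch in node.child_nodes()],
                ancestral=names[id(node)])
        demo.sort_events()
        return demo


# ---------------------------------------------------------------------------
# gene trees


def _ts_to_genetree(ts, pop_names, sample_label, locus_id, path) -> GeneTree:
    t = ts.first()
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    species_map: dict[str, str] = {}

    def build(u):
        node = dendropy.Node()
        if t.is_leaf(u):
            label = sample_label(u)
            taxon = taxon_ns.new_taxon(label)
            node.taxon = taxon
            species_map[label] = pop_names[ts.node(u).population]
        for ch in t.children(u):
            child = build(ch)
            child.edge.length = t.time(u) - t.time(ch)
            node.add_child(child)
        return node

    tree.seed_node = build(t.root)
    return GeneTree(tree=tree, length_unit=COALESCENT, locus_id=locus_id,
                    species_map=species_map, meta={"path": path})


def simulate_gene_trees(network: SpeciesNetwork, n_loci: int, seed: int,
                        samples: dict[str, int] | None = None
                        ) -> list[GeneTree]:
    """Simulate independent gene trees under the MSC on the network.

    Each locus follows the donor parental path with probability ``gamma``;
    the path taken is recorded in ``meta["path"]`` (``"major"`` or
    ``"donor"``).  ``samples`` maps species to haploid sample counts
    (default 1 per species); with k > 1 leaves are labelled
    ``"<species>_<i>"``.

    Returned branch lengths are in coalescent units of 2N generations,
    with per-branch relative sizes rescaling the local coalescent rate.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    gamma = network.hybrid.gamma if network.hybrid is not None else 0.0
    paths = rng.random(n_loci) < gamma

    leaf_labels = network.leaf_labels()
    samples = samples or {sp: 1 for sp in leaf_labels}
    multi = any(k > 1 for k in samples.values())

    def run(tree, n, ms_seed):
        if n == 0:
            return iter(())
        demo = network._demography(tree)
        sample_sets = [msprime.SampleSet(samples.get(sp, 0), population=sp,
                                         ploidy=1)
                       for sp in leaf_labels if samples.get(sp, 0) > 0]
        return msprime.sim_ancestry(
            samples=sample_sets, demography=demo, ploidy=1,
            num_replicates=n, random_seed=ms_seed)

    n_minor = int(paths.sum())
    major_iter = run(network._major_tree(), n_loci - n_minor,
                     int(rng.integers(1, 2**31 - 1)))
    minor_iter = run(network._minor_tree() if network.hybrid else None,
                     n_minor, int(rng.integers(1, 2**31 - 1))) \
        if n_minor else iter(())

    out: list[GeneTree] = []
    for locus, is_minor in enumerate(paths):
        ts = next(minor_iter if is_minor else major_iter)
        pop_names = [p.metadata.get("name", str(p.id))
                     for p in ts.populations()]
        counts: dict[int, int] = {}

        def label(u, counts=counts, ts=ts, pop_names=pop_names):
            p = ts.node(u).population
            sp = pop_names[p]
            if not multi and samples.get(sp, 0) == 1:
                return sp
            i = counts.get(p, 0)
            counts[p] = i + 1
            return f"{sp}_{i}"

        out.append(_ts_to_genetree(ts, pop_names, label, locus,
                                   "donor" if is_minor else "major"))
    return out


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Biallelic variants x individuals with a population map.

    ``genotypes`` holds alt-allele dosage 0/1/2 with -1 for missing.
    Positions are 0-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64
    genotypes: np.ndarray      # (n_sites, n_indiv) int8
    individuals: list[str]
    pop_map: dict[str, str]    # individual -> population
    outgroup: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        pops = set(self.pop_map.values())
        for ind in self.individuals:
            if ind not in self.pop_map:
                raise ValueError(f"individual {ind} missing from pop map")
        if not pops:
            raise ValueError("empty population map")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.pop_map[ind], None)
        return list(seen)

    def members(self, pop: str) -> list[int]:
        return [i for i, ind in enumerate(self.individuals)
                if self.pop_map[ind] == pop]

    def allele_freqs(self, pop: str) -> np.ndarray:
        """Alt-allele frequency per site within a population (NaN where
        every member is missing)."""
        idx = self.members(pop)
        g = self.genotypes[:, idx]
        valid = g >= 0
        alt = np.where(valid, g, 0).sum(axis=1).astype(float)
        n = 2.0 * valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / n, np.nan)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[keep], pos=self.pos[keep],
            genotypes=self.genotypes[keep],
            individuals=list(self.individuals),
            pop_map=dict(self.pop_map), outgroup=self.outgroup,
            meta=dict(self.meta))


def _branch_table(gt: GeneTree, hap_index: dict[str, int]):
    """(mask, length) per edge over haplotype leaves, plus total length."""
    masks, lengths = [], []
    node_mask: dict[int, int] = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            m = 1 << hap_index[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= node_mask[id(ch)]
        node_mask[id(node)] = m
        if node.parent_node is not None and (node.edge.length or 0.0) > 0:
            masks.append(m)
            lengths.append(node.edge.length)
    return masks, np.asarray(lengths, float)


def simulate_genotypes(trees: Sequence[GeneTree], sites_per_locus: int,
                       mut_rate: float, seed: int,
                       gap: int = 0, chrom: str = "chr1",
                       diploid_pairing: bool = False) -> GenotypeMatrix:
    """Drop infinite-sites mutations on the gene trees.

    Mutations fall on branches proportionally to length with rate
    ``mut_rate`` per site per coalescent unit; locus ``i`` occupies the
    interval ``[i*(L+gap), i*(L+gap)+L)`` of a synthetic chromosome.  Each
    haplotype is rendered as a homozygous pseudo-diploid (dosage 0/2)
    unless ``diploid_pairing`` is set, in which case consecutive haplotype
    pairs ``sp_0, sp_1`` form diploid individuals.
    """
    if mut_rate < 0:
        raise ValueError("mut_rate must be >= 0")
    rng = np.random.default_rng(seed)
    L = sites_per_locus

    first = trees[0]
    hap_labels = sorted(first.leaf_labels())
    hap_index = {h: i for i, h in enumerate(hap_labels)}
    species_map = dict(first.species_map) or {h: h for h in hap_labels}

    if diploid_pairing:
        pairs: dict[str, list[str]] = {}
        for h in hap_labels:
            sp = species_map.get(h, h)
            pairs.setdefault(sp, []).append(h)
        individuals, pair_idx, pop_map = [], [], {}
        for sp, haps in pairs.items():
            if len(haps) == 1:
                # lone haplotype renders as a homozygous pseudo-diploid
                name = f"{sp}-0"
                individuals.append(name)
                pair_idx.append((hap_index[haps[0]], hap_index[haps[0]]))
                pop_map[name] = sp
                continue
            if len(haps) % 2:
                raise ValueError(f"odd haplotype count for {sp}")
            for j in range(0, len(haps), 2):
                name = f"{sp}-{j // 2}"
                individuals.append(name)
                pair_idx.append((hap_index[haps[j]], hap_index[haps[j + 1]]))
                pop_map[name] = sp
    else:
        individuals = hap_labels
        pair_idx = [(hap_index[h], hap_index[h]) for h in hap_labels]
        pop_map = {h: species_map.get(h, h) for h in hap_labels}

    all_pos: list[int] = []
    all_rows: list[np.ndarray] = []
    for i, gt in enumerate(trees):
        masks, lengths = _branch_table(gt, hap_index)
        total = lengths.sum()
        if total <= 0 or mut_rate == 0:
            continue
        n_mut = rng.poisson(mut_rate * L * total)
        n_mut = min(n_mut, L)  # infinite-sites cap: one mutation per site
        if n_mut == 0:
            continue
        which = rng.choice(len(masks), size=n_mut, p=lengths / total)
        offs = np.sort(rng.choice(L, size=n_mut, replace=False))
        start = i * (L + gap)
        for off, b in zip(offs, which):
            m = masks[b]
            row = np.zeros(len(individuals), dtype=np.int8)
            for k, (h1, h2) in enumerate(pair_idx):
                row[k] = ((m >> h1) & 1) + ((m >> h2) & 1)
            if not diploid_pairing:
                pass  # h1 == h2 already doubles the dosage
            all_pos.append(start + int(off))
            all_rows.append(row)

    if not all_pos:
        geno = np.zeros((0, len(individuals)), dtype=np.int8)
        pos = np.zeros(0, dtype=np.int64)
    else:
        pos = np.asarray(all_pos, dtype=np.int64)
        geno = np.vstack(all_rows)
    chrom_arr = np.full(len(pos), chrom)
    outgroup = first.meta.get("outgroup")
    return GenotypeMatrix(chrom=chrom_arr, pos=pos, genotypes=geno,
                         individuals=individuals, pop_map=pop_map,
                         outgroup=outgroup,
                         meta={"sites_per_locus": L, "gap": gap,
                               "n_loci": len(trees)})


# ---------------------------------------------------------------------------
# admixed panel


@dataclass
class AdmixtureTruth:
    """Ground truth for a simulated admixed panel."""

    tracts: dict[str, list[tuple[int, int]]]  # individual -> source-2 bp runs
    dosage: np.ndarray                        # (n_sites, n_admixed) true 0/1/2
    source2_proportion: float


def simulate_admixed_panel(source_divergence: float, admix_fraction: float,
                           n_generations: int, recomb_rate: float, seed: int,
                           n_sites: int = 2000, chrom_length: int = 2_000_000,
                           n_source: int = 10, n_admixed: int = 5,
                           chrom: str = "chr1"
                           ) -> tuple[GenotypeMatrix, AdmixtureTruth]:
    """Two source panels plus admixed mosaics with known ancestry tracts.

    Ancestry switches along each admixed haplotype at Poisson rate
    ``n_generations * recomb_rate`` per bp, redrawing the source with
    probability ``admix_fraction`` for source 2; tract lengths are
    therefore exponential with mean ``1/(n_generations*recomb_rate)``.
    Site frequencies in the two sources follow a Balding-Nichols model
    with F = 1 - exp(-source_divergence); ``source_divergence=inf`` gives
    fixed differences (source1 ancestral, source2 derived at every site).
    """
    if not 0.0 < admix_fraction < 1.0:
        raise ValueError("admix_fraction must be strictly inside (0,1)")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_length, size=n_sites, replace=False))

    if np.isinf(source_divergence):
        f1 = np.zeros(n_sites)
        f2 = np.ones(n_sites)
    else:
        F = 1.0 - np.exp(-source_divergence)
        F = min(max(F, 1e-9), 1 - 1e-9)
        p = rng.uniform(0.05, 0.95, size=n_sites)
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        f1 = rng.beta(a, b)
        f2 = rng.beta(a, b)

    def panel(f, n):
        return rng.binomial(2, f[:, None], size=(n_sites, n)).astype(np.int8)

    g1 = panel(f1, n_source)
    g2 = panel(f2, n_source)

    lam = n_generations * recomb_rate
    tracts: dict[str, list[tuple[int, int]]] = {}
    adm_cols = []
    true_dose = np.zeros((n_sites, n_admixed), dtype=np.int8)
    for k in range(n_admixed):
        name = f"adm-{k}"
        dose = np.zeros(n_sites, dtype=np.int8)
        geno = np.zeros(n_sites, dtype=np.int8)
        runs: list[tuple[int, int]] = []
        for _hap in range(2):
            # breakpoints along the chromosome
            if lam > 0:
                n_bp = rng.poisson(lam * chrom_length)
                bps = np.sort(rng.uniform(0, chrom_length, size=n_bp))
            else:
                bps = np.array([])
            edges = np.concatenate([[0.0], bps, [float(chrom_length)]])
            states = rng.random(len(edges) - 1) < admix_fraction  # True=src2
            seg_of_site = np.searchsorted(edges, pos, side="right") - 1
            anc2 = states[seg_of_site]
            allele = np.where(anc2, rng.random(n_sites) < f2,
                              rng.random(n_sites) < f1).astype(np.int8)
            geno += allele
            dose += anc2.astype(np.int8)
            for s, e, st in zip(edges[:-1], edges[1:], states):
                if st:
                    runs.append((int(s), int(np.ceil(e))))
        # merge overlapping per-individual source-2 runs
        runs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in runs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        tracts[name] = merged
        true_dose[:, k] = dose
        adm_cols.append(geno)

    genotypes = np.hstack([g1, g2, np.column_stack(adm_cols)])
    individuals = [f"src1-{i}" for i in range(n_source)] + \
                  [f"src2-{i}" for i in range(n_source)] + \
                  [f"adm-{i}" for i in range(n_admixed)]
    pop_map = {}
    for ind in individuals:
        pop_map[ind] = ind.rsplit("-", 1)[0]
    gm = GenotypeMatrix(chrom=np.full(n_sites, chrom), pos=pos,
                        genotypes=genotypes, individuals=individuals,
                        pop_map=pop_map,
                        meta={"chrom_length": chrom_length})
    prop = float(true_dose.mean() / 2.0)
    return gm, AdmixtureTruth(tracts=tracts, dosage=true_dose,
                              source2_proportion=prop)
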