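"""Genomic windows, per-window gene-tree inference and topology tables.

Window trees are inferred with neighbor-joining on Jukes-Cantor corrected
distances between per-species consensus sequences.  This recovers what the
downstream statistics consume from window trees -- topologies and internal
branch lengths -- without a full ML substitution-model fit; the dialect
difference is documented in the methods note.  Windows with fewer
parsimony-informative sites than a configurable minimum (default 10) are
filtered rather than inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import skbio
from skbio import DistanceMatrix

from .simnet import GenotypeMatrix
from .trees import (SUBS_PER_SITE, GeneTree, canonical_topology,
                    root_with_outgroup, tree_from_newick)

__all__ = [
    "WindowSpec",
    "TopologyTable",
    "make_windows",
    "species_consensus",
    "count_informative_sites",
    "infer_window_tree",
    "infer_window_trees",
    "tabulate_topologies",
]

# JC distance saturates at p = 3/4; cap there minus epsilon
_P_SAT = 0.75
_D_CAP = 5.0


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom, pos) -> np.ndarray:
        return (chrom == self.chrom) & (pos >= self.start) & (pos < self.end)


def make_windows(chrom_lengths: dict[str, int], size: int,
                 gap: int = 0) -> list[WindowSpec]:
    """Tile [0, L) with windows of ``size`` bp separated by ``gap`` bp.

    Windows start at 0 with stride ``size+gap``; a trailing partial window
    is dropped.  ``gap=0`` gives the non-overlapping tiling used for
    200-kb window trees; ``gap=400_000`` with ``size=20_000`` gives the
    recombination-sparse scheme used for triplet branch-length input.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    out = []
    for chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        start = 0
        while start + size <= L:
            out.append(WindowSpec(chrom, start, start + size))
            start += size + gap
    return out


# ---------------------------------------------------------------------------
# consensus alleles and informative sites


def species_consensus(gm: GenotypeMatrix,
                      mask: np.ndarray | None = None
                      ) -> tuple[list[str], np.ndarray]:
    """Majority consensus allele (0/1) per species per site.

    Dosage majority within each species; exact ties and all-missing sites
    yield -1 (undefined) for that species so they can be excluded from
    informative-site counts and distances deterministically.
    """
    pops = gm.populations()
    g = gm.genotypes if mask is None else gm.genotypes[mask]
    cons = np.full((g.shape[0], len(pops)), -1, dtype=np.int8)
    for j, pop in enumerate(pops):
        idx = gm.members(pop)
        sub = g[:, idx].astype(np.int16)
        valid = sub >= 0
        alt = np.where(valid, sub, 0).sum(axis=1)
        tot = 2 * valid.sum(axis=1)
        ref = tot - alt
        cons[alt > ref, j] = 1
        cons[ref > alt, j] = 0
        cons[tot == 0, j] = -1
        cons[(alt == ref) & (tot > 0), j] = -1  # tie -> excluded
    return pops, cons


def _informative_mask(cons: np.ndarray) -> np.ndarray:
    """Parsimony-informative flags: >=2 alleles each seen in >=2 species."""
    n0 = (cons == 0).sum(axis=1)
    n1 = (cons == 1).sum(axis=1)
    return (n0 >= 2) & (n1 >= 2)


def count_informative_sites(gm: GenotypeMatrix, window: WindowSpec) -> int:
    in_win = window.contains(gm.chrom, gm.pos)
    if not in_win.any():
        return 0
    _, cons = species_consensus(gm, in_win)
    return int(_informative_mask(cons).sum())


# ---------------------------------------------------------------------------
# NJ tree inference


def _jc_distance(p: float) -> float:
    if p >= _P_SAT:
        return _D_CAP
    if p <= 0:
        return 0.0
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def infer_window_tree(gm: GenotypeMatrix, window: WindowSpec, outgroup: str,
                      min_informative: int = 10,
                      window_span: int | None = None) -> GeneTree | None:
    """NJ tree on JC-corrected consensus distances for one window.

    Returns ``None`` (window filtered) when the parsimony-informative site
    count is below ``min_informative``.  Branch lengths are substitutions
    per site using the window span (variant + invariant positions) as the
    sequence length; saturated distances are capped.  The returned tree is
    rooted on the outgroup and deterministic in the input.
    """
    in_win = window.contains(gm.chrom, gm.pos)
    pops, cons = species_consensus(gm, in_win)
    if outgroup not in pops:
        raise ValueError(f"outgroup {outgroup!r} not a population")
    n_inf = int(_informative_mask(cons).sum())
    if n_inf < min_informative:
        return None
    span = window_span or window.length
    k = len(pops)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = (cons[:, i] >= 0) & (cons[:, j] >= 0)
            diff = int((cons[ok, i] != cons[ok, j]).sum())
            p = diff / span
            dm[i, j] = dm[j, i] = _jc_distance(p)
    order = sorted(range(k), key=lambda i: pops[i])
    labels = [pops[i] for i in order]
    dmat = DistanceMatrix(dm[np.ix_(order, order)], ids=labels)
    njt = skbio.tree.nj(dmat)
    gt = tree_from_newick(str(njt), length_unit=SUBS_PER_SITE)
    for edge in gt.tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0  # NJ can emit tiny negatives
    gt = root_with_outgroup(gt, outgroup)
    gt.locus_id = f"{window.chrom}:{window.start}-{window.end}"
    gt.meta["n_informative"] = n_inf
    return gt


def infer_window_trees(gm: GenotypeMatrix, windows: Sequence[WindowSpec],
                       outgroup: str, min_informative: int = 10
                       ) -> list[tuple[WindowSpec, GeneTree | None]]:
    return [(w, infer_window_tree(gm, w, outgroup, min_informative))
            for w in windows]


# ---------------------------------------------------------------------------
# topology tabulation


@dataclass
class TopologyTable:
    """Canonical topology string -> count, with rank order."""

    counts: dict[str, int]
    n_trees: int
    n_rejected: int = 0

    @property
    def frequencies(self) -> dict[str, float]:
        tot = sum(self.counts.values())
        return {t: c / tot for t, c in self.counts.items()} if tot else {}

    def ranked(self) -> list[tuple[str, int, float]]:
        freqs = self.frequencies
        return sorted(((t, c, freqs[t]) for t, c in self.counts.items()),
                      key=lambda x: (-x[1], x[0]))

    def top(self, k: int = 2) -> list[str]:
        return [t for t, _, _ in self.ranked()[:k]]


def tabulate_topologies(trees: Iterable[GeneTree],
                        outgroup: str | None = None) -> TopologyTable:
    """Count canonical (outgroup-rooted, length-free) topologies.

    Trees whose species set differs from the first tree's are rejected
    per-tree and counted in ``n_rejected``.
    """
    counts: dict[str, int] = {}
    ref_set: set[str] | None = None
    n = 0
    rejected = 0
    for gt in trees:
        species = {gt.species_of(l) for l in gt.leaf_labels()}
        if ref_set is None:
            ref_set = species
        if species != ref_set:
            rejected += 1
            continue
        key = canonical_topology(gt, outgroup=outgroup)
        counts[key] = counts.get(key, 0) + 1
        n += 1
    return TopologyTable(counts=counts, n_trees=n, n_rejected=rejected)
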