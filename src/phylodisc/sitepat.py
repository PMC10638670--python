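"""Site-pattern introgression statistics.

Frequency-weighted ABBA-BABA arithmetic on polarised derived-allele
frequencies: Patterson's D with a delete-one block jackknife, the
f4-admixture ratio and its f-branch summary over a species tree, the
windowed F_d statistic with the dynamic-donor convention, Hudson's FST
(ratio of averages) and per-individual heterozygosity windows.

All pattern weights use population allele frequencies (Dsuite-style
population mode): for ordered taxa (P1, P2, P3, O) with derived
frequencies p1..p3 (the outgroup is ancestral after polarisation),

    ABBA = (1 - p1) p2 p3,     BABA = p1 (1 - p2) p3,

and D = sum(ABBA - BABA) / sum(ABBA + BABA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .simnet import GenotypeMatrix
from .trees import GeneTree, TreeArrays, build_index
from .winphylo import WindowSpec

__all__ = [
    "PolarizedFreqs",
    "DStatResult",
    "WindowStat",
    "polarize",
    "patterson_d",
    "enumerate_trios",
    "f4_ratio",
    "f_branch",
    "fd_windows",
    "top_fraction",
    "hudson_fst",
    "heterozygosity_windows",
]

DEFAULT_BLOCK_SIZE = 1_000_000
MIN_BLOCKS_FOR_Z = 20


@dataclass
class PolarizedFreqs:
    """Per-site derived-allele frequencies per population.

    Sites where the outgroup was polymorphic or missing have been
    dropped; frequencies are NaN for populations with no data at a site.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: list[str]
    freqs: np.ndarray  # (n_sites, n_pops)
    outgroup: str

    def pop(self, name: str) -> np.ndarray:
        return self.freqs[:, self.pops.index(name)]

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def polarize(gm: GenotypeMatrix, outgroup: str | None = None) -> PolarizedFreqs:
    """Derived-allele frequencies relative to the outgroup consensus.

    Sites where the outgroup population is missing or polymorphic
    (either segregating among outgroup individuals or heterozygous) are
    dropped; where the outgroup is fixed for the alternate allele the
    frequencies flip.
    """
    outgroup = outgroup or gm.outgroup
    if outgroup is None:
        raise ValueError("no outgroup designated")
    og_idx = gm.members(outgroup)
    if not og_idx:
        raise ValueError(f"outgroup population {outgroup!r} is empty")
    og = gm.genotypes[:, og_idx]
    valid = og >= 0
    any_data = valid.any(axis=1)
    fixed_ref = np.where(valid, og == 0, True).all(axis=1) & any_data
    fixed_alt = np.where(valid, og == 2, True).all(axis=1) & any_data
    keep = fixed_ref | fixed_alt
    if not keep.any():
        import warnings
        warnings.warn("all sites dropped during polarization")
    pops = gm.populations()
    freqs = np.column_stack([gm.allele_freqs(p)[keep] for p in pops])
    flip = fixed_alt[keep]
    freqs[flip] = 1.0 - freqs[flip]
    return PolarizedFreqs(chrom=gm.chrom[keep], pos=gm.pos[keep], pops=pops,
                          freqs=freqs, outgroup=outgroup)


# ---------------------------------------------------------------------------
# Patterson's D


@dataclass
class DStatResult:
    """Patterson's D with block-jackknife uncertainty."""

    trio: tuple[str, str, str]
    d: float
    se: float
    z: float
    n_blocks: int
    abba: float
    baba: float
    defined: bool = True
    note: str = ""


def _abba_baba(p1, p2, p3):
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    abba = np.where(ok, (1 - p1) * p2 * p3, 0.0)
    baba = np.where(ok, p1 * (1 - p2) * p3, 0.0)
    return abba, baba


def _block_ids(chrom: np.ndarray, pos: np.ndarray, block_size: int):
    ids = np.zeros(len(pos), dtype=np.int64)
    next_id = 0
    for c in dict.fromkeys(chrom.tolist()):
        sel = chrom == c
        b = pos[sel] // block_size
        uniq, inv = np.unique(b, return_inverse=True)
        ids[sel] = inv + next_id
        next_id += len(uniq)
    return ids, next_id


def patterson_d(pf: PolarizedFreqs, p1: str, p2: str, p3: str,
                block_size: int = DEFAULT_BLOCK_SIZE) -> DStatResult:
    """D = sum(ABBA-BABA)/sum(ABBA+BABA) with delete-one block jackknife.

    Fewer than 2 blocks (or a zero denominator) yields an undefined
    result; fewer than ``MIN_BLOCKS_FOR_Z`` blocks is flagged in ``note``
    because the jackknife Z is then unreliable.
    """
    abba, baba = _abba_baba(pf.pop(p1), pf.pop(p2), pf.pop(p3))
    num = float((abba - baba).sum())
    den = float((abba + baba).sum())
    trio = (p1, p2, p3)
    if den == 0:
        return DStatResult(trio, math.nan, math.nan, math.nan, 0,
                           float(abba.sum()), float(baba.sum()),
                           defined=False, note="zero ABBA+BABA total")
    d = num / den
    ids, n_blocks = _block_ids(pf.chrom, pf.pos, block_size)
    if n_blocks < 2:
        return DStatResult(trio, d, math.nan, math.nan, n_blocks,
                           float(abba.sum()), float(baba.sum()),
                           defined=False, note="fewer than 2 jackknife blocks")
    bnum = np.bincount(ids, weights=abba - baba, minlength=n_blocks)
    bden = np.bincount(ids, weights=abba + baba, minlength=n_blocks)
    loo = (num - bnum) / np.where(den - bden > 0, den - bden, np.nan)
    loo = loo[~np.isnan(loo)]
    B = len(loo)
    if B < 2:
        return DStatResult(trio, d, math.nan, math.nan, B,
                           float(abba.sum()), float(baba.sum()),
                           defined=False, note="degenerate jackknife")
    se = math.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum())
    z = d / se if se > 0 else math.inf * np.sign(d) if d else 0.0
    note = "" if B >= MIN_BLOCKS_FOR_Z else \
        f"only {B} jackknife blocks (<{MIN_BLOCKS_FOR_Z}); Z unreliable"
    return DStatResult(trio, d, se, z, B, float(abba.sum()),
                       float(baba.sum()), note=note)


# ---------------------------------------------------------------------------
# trios ordered by a reference topology


def enumerate_trios(species_tree: GeneTree, taxa: Sequence[str]
                    ) -> list[tuple[tuple[str, str, str], bool]]:
    """Order every 3-subset of ``taxa`` as ((M1, M2), M3) by the
    reference topology; the flag marks unresolved triples ordered by the
    alphabetical tie-break.  The combinatorial count is C(n, 3)."""
    index = build_index(sorted({species_tree.species_of(l)
                                for l in species_tree.leaf_labels()}))
    ta = TreeArrays(species_tree, index)
    out = []
    for trio in combinations(sorted(taxa), 3):
        a, b, c = (1 << index[t] for t in trio)
        cherry, length = ta.triplet(a, b, c)
        pair = [t for t in trio if (1 << index[t]) & cherry]
        lone = [t for t in trio if (1 << index[t]) & ~cherry][0]
        flagged = length == 0.0  # unresolved triple -> tie-break ordering
        out.append(((pair[0], pair[1], lone), flagged))
    return out


# ---------------------------------------------------------------------------
# f4 ratio and f-branch


@dataclass
class F4Result:
    taxa: tuple[str, str, str]  # (A, B, C) with implicit outgroup
    ratio: float                # clamped to [0, 1]
    raw: float
    defined: bool = True


def f4_ratio(pf: PolarizedFreqs, a: str, b: str, c: str) -> F4Result:
    """f4-admixture ratio for (((A, B), C), O).

    Numerator: sum(ABBA - BABA) with (A, B, C).  Denominator: the same
    with the donor substituted for B, using the per-site dynamic-donor
    frequency max(pB, pC).  The ratio estimates the fraction of B's
    genome traceable to the donor lineage of C.
    """
    pa, pb, pc = pf.pop(a), pf.pop(b), pf.pop(c)
    abba, baba = _abba_baba(pa, pb, pc)
    pd = np.fmax(pb, pc)
    abba_d, baba_d = _abba_baba(pa, pd, pc)
    num = float((abba - baba).sum())
    den = float((abba_d - baba_d).sum())
    if den == 0:
        return F4Result((a, b, c), math.nan, math.nan, defined=False)
    raw = num / den
    return F4Result((a, b, c), min(max(raw, 0.0), 1.0), raw)


@dataclass
class FBranchCell:
    branch_id: str
    donor: str
    value: float | None
    n_combinations: int


def f_branch(species_tree: GeneTree, pf: PolarizedFreqs,
             taxa: Sequence[str] | None = None) -> list[FBranchCell]:
    """f-branch summary: attribute f4 signals to species-tree branches.

    For branch b (with descendant taxa D(b) and sister taxa S(b)) and
    donor taxon C outside clade(parent(b)),

        f_b(C) = min over B in D(b) of median over A in S(b) of f4(A,B,C),

    the minimum guarding against signals explained by a deeper branch.
    Cells with no valid (A, B, C) combination are empty.
    """
    taxa = sorted(taxa or {species_tree.species_of(l)
                           for l in species_tree.leaf_labels()})
    taxa_set = set(taxa)
    tree = species_tree.tree
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset(
                [species_tree.species_of(node.taxon.label)]) & taxa_set
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= leafsets[id(ch)]
            leafsets[id(node)] = s
    cells = []
    cache: dict[tuple[str, str, str], F4Result] = {}

    def f4(a, b, c):
        key = (a, b, c)
        if key not in cache:
            cache[key] = f4_ratio(pf, a, b, c)
        return cache[key]

    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        D = leafsets[id(node)]
        S = frozenset()
        for sib in parent.child_nodes():
            if sib is not node:
                S |= leafsets[id(sib)]
        if not D or not S:
            continue
        inside = leafsets[id(parent)]
        branch_id = ",".join(sorted(D))
        for donor in taxa:
            if donor in inside:
                continue
            vals_b = []
            n_comb = 0
            for bt in sorted(D):
                ratios = []
                for at in sorted(S):
                    r = f4(at, bt, donor)
                    if r.defined:
                        ratios.append(r.ratio)
                        n_comb += 1
                if ratios:
                    vals_b.append(float(np.median(ratios)))
            value = min(vals_b) if vals_b else None
            cells.append(FBranchCell(branch_id=branch_id, donor=donor,
                                     value=value, n_combinations=n_comb))
    return cells


# ---------------------------------------------------------------------------
# windowed F_d


@dataclass
class WindowStat:
    """A statistic attached to a half-open genomic window."""

    window: WindowSpec
    name: str
    value: float          # NaN when undefined
    n_informative: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def fd_windows(pf: PolarizedFreqs, p1: str, p2: str, p3: str,
               windows: Sequence[WindowSpec]) -> list[WindowStat]:
    """Windowed F_d for (((P1, P2), P3), O).

    Per window, F_d = sum(ABBA-BABA) / sum(ABBA_D-BABA_D) where the donor
    frequency per site is max(p2, p3).  Windows with a non-positive
    denominator or negative numerator are reported undefined (NaN) rather
    than clamped -- the standard convention, which matters for the
    top-fraction tail selection downstream.
    """
    pa, pb, pc = pf.pop(p1), pf.pop(p2), pf.pop(p3)
    abba, baba = _abba_baba(pa, pb, pc)
    pd_ = np.fmax(pb, pc)
    abba_d, baba_d = _abba_baba(pa, pd_, pc)
    informative = (abba + baba) > 0
    out = []
    for w in windows:
        sel = w.contains(pf.chrom, pf.pos)
        num = float((abba[sel] - baba[sel]).sum())
        den = float((abba_d[sel] - baba_d[sel]).sum())
        n_inf = int(informative[sel].sum())
        if den <= 0 or num < 0:
            val = math.nan
        else:
            val = num / den
        out.append(WindowStat(window=w, name="fd", value=val,
                              n_informative=n_inf))
    return out


def top_fraction(stats: Sequence[WindowStat], fraction: float
                 ) -> list[WindowStat]:
    """The ceil(fraction * n_defined) highest-valued windows.

    Ties break by genomic order (earlier coordinate kept), so selection
    is deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    defined = [s for s in stats if s.defined]
    if not defined:
        return []
    k = math.ceil(fraction * len(defined))
    ranked = sorted(defined,
                    key=lambda s: (-s.value, s.window.chrom, s.window.start))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Hudson FST


def _pop_counts(gm: GenotypeMatrix, pop: str):
    idx = gm.members(pop)
    g = gm.genotypes[:, idx]
    valid = g >= 0
    alt = np.where(valid, g, 0).sum(axis=1).astype(float)
    n = 2.0 * valid.sum(axis=1)
    return alt, n


def hudson_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str,
               windows: Sequence[WindowSpec] | None = None):
    """Hudson's FST estimator, ratio of averages across sites.

    Per site with sample allele frequencies p1, p2 and allele counts
    n1, n2 >= 2:

        N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        Dd = p1(1-p2) + p2(1-p1)

    and FST = sum(N)/sum(Dd).  Negative estimates are retained.  With
    ``windows`` a list of per-window :class:`WindowStat` is returned,
    otherwise a single float (NaN when no usable site).
    """
    alt1, n1 = _pop_counts(gm, pop_a)
    alt2, n2 = _pop_counts(gm, pop_b)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / n1
        p2 = alt2 / n2
        N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - \
            p2 * (1 - p2) / (n2 - 1)
        Dd = p1 * (1 - p2) + p2 * (1 - p1)
    N = np.where(ok, N, 0.0)
    Dd = np.where(ok, Dd, 0.0)
    poly = Dd > 0
    if windows is None:
        tot = Dd[poly].sum()
        return float(N[poly].sum() / tot) if tot > 0 else math.nan
    out = []
    for w in windows:
        sel = w.contains(gm.chrom, gm.pos) & poly
        tot = Dd[sel].sum()
        val = float(N[sel].sum() / tot) if tot > 0 else math.nan
        out.append(WindowStat(window=w, name="fst", value=val,
                              n_informative=int(sel.sum())))
    return out


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity_windows(gm: GenotypeMatrix, windows: Sequence[WindowSpec],
                           callable_length: int | None = None
                           ) -> dict[str, list[WindowStat]]:
    """Per-individual heterozygous-call rate per window.

    The denominator is the callable window length, taken as the full
    window size unless overridden (the synthetic genome is fully
    callable); windows of zero callable length are undefined.
    """
    out: dict[str, list[WindowStat]] = {ind: [] for ind in gm.individuals}
    for w in windows:
        sel = w.contains(gm.chrom, gm.pos)
        L = callable_length if callable_length is not None else w.length
        g = gm.genotypes[sel]
        for j, ind in enumerate(gm.individuals):
            if L <= 0:
                val = math.nan
                n_het = 0
            else:
                n_het = int((g[:, j] == 1).sum())
                val = n_het / L
            out[ind].append(WindowStat(window=w, name="heterozygosity",
                                       value=val, n_informative=n_het))
    return out
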