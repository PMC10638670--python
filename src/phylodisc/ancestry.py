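"""Local-ancestry dosage inference and introgression-tract calling.

A two-source hidden Markov model assigns each site of an admixed diploid
an expected dosage (0-2) of source-2 ancestry.  Haplotypes switch source
at rate ``g * recomb_rate`` per bp (g = generations since admixture);
the diploid chain is the product of two exchangeable haplotype chains,
so it has three states (0, 1 or 2 source-2 haplotypes).  Emissions come
from panel allele frequencies with pseudocounts.  The forward-backward
recursion is written directly because transition and emission terms vary
site-by-site with physical distance and panel frequencies.

Post-processing follows fixed rules: dosages are averaged over runs with
different g values, sites with dosage strictly above 1.5 toward either
source are introgression sites, per-window sums of those dosages rank
10-kb windows, the top 1% become putative tracts, and tracts intersected
with the F_d top tail give the final candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simnet import GenotypeMatrix
from .sitepat import WindowStat, top_fraction
from .winphylo import WindowSpec
from .trees import GeneTree

__all__ = [
    "AncestryTrack",
    "TractSet",
    "infer_dosage",
    "call_sites",
    "call_tracts",
    "intersect_candidates",
    "partition_trees",
]

DOSAGE_THRESHOLD = 1.5
TRACT_FRACTION = 0.01
PSEUDOCOUNT = 0.5


@dataclass
class AncestryTrack:
    """Per-site expected source-2 dosage for one admixed individual."""

    individual: str
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray          # (n_sites,) in [0, 2]
    g_values: tuple
    n_runs: int


@dataclass
class TractSet:
    """Top-fraction windows by summed above-threshold dosage."""

    windows: list[WindowStat]        # all evaluated windows with sums
    selected: list[WindowStat]       # the chosen top fraction
    fraction: float
    source: int                      # 1 or 2
    degenerate: bool = False         # all sums zero


def _hap_transition(q: float, prior2: float) -> np.ndarray:
    """2x2 haplotype chain step: switch happens with prob q, after which
    the source is redrawn from the (prior1, prior2) mixture proportions."""
    p1, p2 = 1 - prior2, prior2
    return np.array([[1 - q + q * p1, q * p2],
                     [q * p1, 1 - q + q * p2]])


def _diploid_transition(M: np.ndarray) -> np.ndarray:
    """3x3 chain over the number of source-2 haplotypes, two independent
    exchangeable haplotypes each stepping by ``M``."""
    T = np.zeros((3, 3))
    for k in range(3):
        # haplotype source vector for state k: k copies of src2
        for a in (0, 1):       # first hap destination (0=src1)
            for b in (0, 1):
                if k == 0:
                    p = M[0, a] * M[0, b]
                elif k == 2:
                    p = M[1, a] * M[1, b]
                else:
                    p = M[1, a] * M[0, b]
                T[k, a + b] += p
    return T


def _emission_probs(g_obs: int, f1: float, f2: float) -> np.ndarray:
    """P(genotype | k source-2 haplotypes) for k = 0, 1, 2."""
    def hap_mix(k):
        # allele-count pmf over {0,1,2} for k src2 + (2-k) src1 haplotypes
        probs = np.zeros(3)
        for a in (0, 1):
            pa = f2 if k >= 1 else f1
            pa = pa if a == 1 else 1 - pa
            for b in (0, 1):
                pb = f2 if k == 2 else f1
                pb = pb if b == 1 else 1 - pb
                probs[a + b] += pa * pb
        return probs
    if g_obs < 0:
        return np.ones(3)
    return np.array([hap_mix(k)[g_obs] for k in (0, 1, 2)])


def _panel_freqs(gm: GenotypeMatrix, pop: str) -> np.ndarray:
    idx = gm.members(pop)
    g = gm.genotypes[:, idx]
    valid = g >= 0
    alt = np.where(valid, g, 0).sum(axis=1).astype(float)
    n = 2.0 * valid.sum(axis=1)
    return (alt + PSEUDOCOUNT) / (n + 2 * PSEUDOCOUNT)


def _forward_backward(obs, pos, f1, f2, lam, prior2):
    n = len(obs)
    post = np.zeros((n, 3))
    pi0 = np.array([(1 - prior2) ** 2, 2 * prior2 * (1 - prior2),
                    prior2 ** 2])
    # precompute emissions
    E = np.empty((n, 3))
    for i in range(n):
        E[i] = _emission_probs(obs[i], f1[i], f2[i])
    alpha = np.empty((n, 3))
    scale = np.empty(n)
    a = pi0 * E[0]
    scale[0] = a.sum() or 1e-300
    alpha[0] = a / scale[0]
    Ts = []
    for i in range(1, n):
        d = max(int(pos[i] - pos[i - 1]), 1)
        q = 1.0 - math.exp(-lam * d)
        T = _diploid_transition(_hap_transition(q, prior2))
        Ts.append(T)
        a = (alpha[i - 1] @ T) * E[i]
        scale[i] = a.sum() or 1e-300
        alpha[i] = a / scale[i]
    beta = np.empty((n, 3))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        b = Ts[i] @ (E[i + 1] * beta[i + 1])
        s = b.sum() or 1e-300
        beta[i] = b / s
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def infer_dosage(gm: GenotypeMatrix, admixed_pop: str, source1: str,
                 source2: str, g, recomb_rate: float,
                 n_runs: int = 3, seed: int = 0,
                 prior2: float = 0.5) -> list[AncestryTrack]:
    """Posterior mean source-2 dosage per admixed individual.

    ``g`` is either a scalar or a list of generation values, one per run
    (mirroring the three-value averaging scheme); runs differ only
    through g, and their posterior dosages are averaged.  Monomorphic
    panels everywhere make the posterior uninformative and are flagged
    via a ValueError.
    """
    g_list = list(np.atleast_1d(np.asarray(g, dtype=float)))
    if len(g_list) == 1:
        g_list = g_list * n_runs
    if len(g_list) != n_runs:
        raise ValueError("need one g per run (or a single scalar)")
    if any(gv <= 0 for gv in g_list):
        raise ValueError("g must be > 0")
    f1 = _panel_freqs(gm, source1)
    f2 = _panel_freqs(gm, source2)
    if np.allclose(f1, f2):
        raise ValueError("panels are indistinguishable at every site "
                         "(monomorphic difference); dosage uninformative")
    tracks = []
    order = np.lexsort((gm.pos, gm.chrom))
    for i in gm.members(admixed_pop):
        ind = gm.individuals[i]
        obs_all = gm.genotypes[:, i]
        dose = np.zeros(gm.n_sites)
        for gv in g_list:
            lam = gv * recomb_rate
            for c in np.unique(gm.chrom):
                sel = np.where(gm.chrom == c)[0]
                post = _forward_backward(obs_all[sel], gm.pos[sel],
                                         f1[sel], f2[sel], lam, prior2)
                dose[sel] += post @ np.array([0.0, 1.0, 2.0])
        dose /= len(g_list)
        tracks.append(AncestryTrack(individual=ind, chrom=gm.chrom,
                                    pos=gm.pos, dosage=dose,
                                    g_values=tuple(g_list),
                                    n_runs=n_runs))
    return tracks


def call_sites(track: AncestryTrack, threshold: float = DOSAGE_THRESHOLD,
               source: int = 2) -> np.ndarray:
    """Indices of introgression sites: dosage strictly above ``threshold``
    toward the requested source (source-1 dosage is 2 - source-2)."""
    d = track.dosage if source == 2 else 2.0 - track.dosage
    return np.where(d > threshold)[0]


def call_tracts(tracks: Sequence[AncestryTrack],
                windows: Sequence[WindowSpec],
                fraction: float = TRACT_FRACTION,
                threshold: float = DOSAGE_THRESHOLD,
                source: int = 2) -> TractSet:
    """Top-fraction windows by the summed above-threshold dosage.

    The per-window statistic sums, over all admixed individuals, the
    dosage values at sites exceeding the threshold toward the source.
    An all-zero statistic still returns ceil(fraction*n) lowest-
    coordinate windows but is flagged degenerate.
    """
    stats = []
    for w in windows:
        total = 0.0
        n_inf = 0
        for tr in tracks:
            sel = w.contains(tr.chrom, tr.pos)
            d = tr.dosage[sel] if source == 2 else 2.0 - tr.dosage[sel]
            above = d > threshold
            total += float(d[above].sum())
            n_inf += int(above.sum())
        stats.append(WindowStat(window=w, name="dosage_sum", value=total,
                                n_informative=n_inf))
    selected = top_fraction(stats, fraction)
    degenerate = all(s.value == 0.0 for s in stats)
    return TractSet(windows=stats, selected=selected, fraction=fraction,
                    source=source, degenerate=degenerate)


def intersect_candidates(tracts: TractSet, fd_top: Sequence[WindowStat]
                         ) -> list[WindowSpec]:
    """Window-wise intersection of the tract selection with the F_d top
    tail; both selections must come from the same window grid."""
    grid = {s.window for s in tracts.windows}
    for s in fd_top:
        if s.window not in grid:
            raise ValueError("F_d selection uses a different window grid")
    chosen = {s.window for s in tracts.selected}
    out = [s.window for s in fd_top if s.window in chosen]
    return sorted(out)


def partition_trees(gm: GenotypeMatrix, regions: Sequence[WindowSpec],
                    outgroup: str, min_variants: int = 50,
                    min_informative: int = 2
                    ) -> tuple[GeneTree, GeneTree]:
    """NJ trees from introgressed-region vs non-introgressed variants.

    Splits the variants by membership in the candidate regions and
    infers one tree from each partition with the window-tree engine
    (whole partition treated as a single window).  Refuses partitions
    below ``min_variants``.
    """
    from .winphylo import infer_window_tree

    inside = np.zeros(gm.n_sites, dtype=bool)
    for w in regions:
        inside |= w.contains(gm.chrom, gm.pos)
    parts = {}
    for name, keep in (("introgressed", inside),
                       ("non-introgressed", ~inside)):
        n = int(keep.sum())
        if n < min_variants:
            raise ValueError(
                f"{name} partition has {n} variants (< {min_variants})")
        sub = gm.subset_sites(keep)
        span = int(sub.pos.max() - sub.pos.min() + 1)
        w = WindowSpec(chrom=str(sub.chrom[0]), start=int(sub.pos.min()),
                       end=int(sub.pos.max()) + 1)
        tree = infer_window_tree(sub, w, outgroup,
                                 min_informative=min_informative,
                                 window_span=span)
        if tree is None:
            raise ValueError(f"{name} partition below informative minimum")
        parts[name] = tree
    return parts["introgressed"], parts["non-introgressed"]
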