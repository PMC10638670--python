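"""Triplet internal-branch-length mixture classification (ILS vs
ILS + introgression).

For each species triplet, every gene tree restricted to the triplet
contributes a topology class (concordant with the species tree, or one
of the two discordant resolutions) and the length of the triplet's
internal branch.  Under the multispecies coalescent, internal branches
of discordance-generating genealogies are exponential starting at zero;
branches produced by a genuine (introgression or speciation) divergence
concentrate at a positive offset.  Each class's branch-length sample is
therefore fit with

    M1:  Exp(lambda)                                   (ILS only)
    M2:  pi * Exp(lambda) + (1-pi) * [c + Exp(lambda)] (ILS + non-ILS)

sharing one scale lambda, with mixture weight pi on the ILS component
and location c >= 0.  Model choice is by BIC with the +-10 decision
band: Delta = BIC_M2 - BIC_M1; Delta > 10 prefers ILS-only, Delta < -10
prefers ILS + introgression, anything between is indistinguishable.
The introgressed-locus fraction of a class is (1 - pi) times the class's
genomic topology frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .trees import GeneTree, TreeArrays, build_index

__all__ = [
    "MixtureFit",
    "TripletClassResult",
    "triplet_branch_lengths",
    "fit_exponential",
    "fit_mixture",
    "classify",
    "introgressed_fraction",
    "run_quibl",
]

ILS_ONLY = "ILS-only"
ILS_PLUS = "ILS+introgression"
INDISTINGUISHABLE = "indistinguishable"

DELTA_BIC_BAND = 10.0
DEFAULT_MIN_N = 30
EM_TOL = 1e-8
EM_MAX_ITER = 500
DEFAULT_N_STARTS = 10


# ---------------------------------------------------------------------------
# branch-length extraction


def triplet_branch_lengths(trees: Sequence[GeneTree],
                           triplet: tuple[str, str, str],
                           species_tree: GeneTree
                           ) -> dict[str, dict]:
    """Per-topology-class internal-branch-length samples for a triplet.

    Returns ``{class_key: {"pair": (x, y), "lengths": array,
    "concordant": bool, "n_polytomy": int}}`` where ``pair`` is the
    cherry of the restricted triplet.  Zero-length internal branches are
    retained as observable zeros; polytomies fall in the class of the
    lexicographically smallest pair and are counted.
    """
    trip = tuple(sorted(triplet))
    index = build_index(trip)
    bits = {t: 1 << index[t] for t in trip}
    sp_ta = TreeArrays(species_tree, build_index(sorted(
        {species_tree.species_of(l) for l in species_tree.leaf_labels()})))
    sp_index = sp_ta.index
    sp_cherry, _ = sp_ta.triplet(*(1 << sp_index[t] for t in trip))
    conc_pair = frozenset(t for t in trip if (1 << sp_index[t]) & sp_cherry)

    classes: dict[frozenset, dict] = {}
    for pair in combinations(trip, 2):
        key = frozenset(pair)
        classes[key] = {"pair": tuple(sorted(pair)), "lengths": [],
                        "concordant": key == conc_pair, "n_polytomy": 0}
    for gt in trees:
        ta = TreeArrays(gt, index)
        if ta.present != (1 << len(trip)) - 1:
            continue  # triplet not fully represented
        cherry, length = ta.triplet(bits[trip[0]], bits[trip[1]],
                                    bits[trip[2]])
        pair = frozenset(t for t in trip if bits[t] & cherry)
        classes[pair]["lengths"].append(length)
        if length == 0.0:
            classes[pair]["n_polytomy"] += 1
    out = {}
    for key, rec in classes.items():
        rec["lengths"] = np.asarray(rec["lengths"], dtype=float)
        out["|".join(rec["pair"])] = rec
    return out


# ---------------------------------------------------------------------------
# model fits


@dataclass
class MixtureFit:
    """Fit record for one branch-length sample (both models)."""

    n: int
    lambda_m1: float
    loglik_m1: float
    bic_m1: float
    lambda_m2: float
    c: float
    pi: float
    loglik_m2: float
    bic_m2: float
    delta_bic: float
    decision: str
    converged: bool = True
    note: str = ""


def fit_exponential(x: np.ndarray) -> tuple[float, float]:
    """MLE of Exp(lambda) (rate parameterisation); returns (lambda, logL)."""
    n = len(x)
    mean = float(x.mean())
    if mean <= 0:
        # all-zero sample: likelihood unbounded; report a capped rate
        lam = 1e8
        return lam, n * math.log(lam)
    lam = 1.0 / mean
    return lam, n * math.log(lam) - lam * float(x.sum())


def _mixture_loglik(x, lam, c, pi):
    f1 = lam * np.exp(-lam * x)
    f2 = np.where(x >= c, lam * np.exp(-lam * np.maximum(x - c, 0.0)), 0.0)
    dens = pi * f1 + (1 - pi) * f2
    if np.any(dens <= 0):
        return -math.inf
    return float(np.log(dens).sum())


def _em_fixed_c(x, c, lam0, pi0, tol=EM_TOL, max_iter=EM_MAX_ITER):
    """EM over (pi, lambda) with the shift c held fixed."""
    lam, pi = lam0, pi0
    ll_old = -math.inf
    converged = False
    for _ in range(max_iter):
        f1 = lam * np.exp(-lam * x)
        f2 = np.where(x >= c, lam * np.exp(-lam * np.maximum(x - c, 0.0)),
                      0.0)
        w1 = pi * f1
        w2 = (1 - pi) * f2
        tot = w1 + w2
        tot = np.where(tot > 0, tot, 1e-300)
        r = w1 / tot
        pi = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        denom = float((r * x).sum() + ((1 - r) * np.maximum(x - c, 0)).sum())
        lam = len(x) / denom if denom > 0 else 1e8
        ll = _mixture_loglik(x, lam, c, pi)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return lam, pi, ll, converged


def fit_mixture(lengths: np.ndarray, n_starts: int = DEFAULT_N_STARTS,
                seed: int = 0, min_n: int = DEFAULT_MIN_N) -> MixtureFit:
    """Fit M1 and M2 to a branch-length sample and apply the BIC rule.

    M2 is fit by EM over (pi, lambda) with the location c profiled on a
    quantile grid of the data and then refined locally; ``n_starts``
    random (pi, lambda) initialisations per c guard against local
    optima.  Samples below ``min_n`` return the indistinguishable
    decision with an insufficient-data flag.  BIC = k ln(n) - 2 logL
    with k = 1 (M1) and k = 3 (M2).
    """
    x = np.asarray(lengths, dtype=float)
    n = len(x)
    if n < min_n:
        return MixtureFit(n=n, lambda_m1=math.nan, loglik_m1=math.nan,
                          bic_m1=math.nan, lambda_m2=math.nan, c=math.nan,
                          pi=math.nan, loglik_m2=math.nan, bic_m2=math.nan,
                          delta_bic=math.nan, decision=INDISTINGUISHABLE,
                          note=f"insufficient data (n={n} < {min_n})")
    lam1, ll1 = fit_exponential(x)
    bic1 = 1 * math.log(n) - 2 * ll1

    rng = np.random.default_rng(seed)
    pos = x[x > 0]
    if len(pos) == 0:
        # degenerate all-zero sample: M2 cannot improve on M1
        ll2, lam2, c_best, pi_best, conv = ll1, lam1, 0.0, 1.0 - 1e-6, True
    else:
        grid = np.unique(np.quantile(pos, np.linspace(0.05, 0.95, 13)))
        grid = np.concatenate([[0.0], grid])
        best = (-math.inf, lam1, 0.0, 0.5, True)
        for c in grid:
            for s in range(n_starts):
                pi0 = rng.uniform(0.1, 0.9) if s else 0.5
                lam0 = lam1 * rng.uniform(0.5, 2.0) if s else lam1
                lam, pi, ll, conv = _em_fixed_c(x, c, lam0, pi0)
                if ll > best[0]:
                    best = (ll, lam, c, pi, conv)
        # zoom refinement: the profile over c is sharply peaked (its
        # optimum sits at an order statistic of the shifted component),
        # so scan two finer brackets and the data values inside them
        ll_b, lam_b, c_b, pi_b, conv_b = best
        full = np.sort(np.concatenate([[0.0], grid]))
        for _zoom in range(2):
            i = int(np.searchsorted(full, c_b))
            lo = full[max(i - 1, 0)] if c_b > full[0] else 0.0
            hi = full[min(i + 1, len(full) - 1)] if c_b < full[-1] \
                else c_b + (full[-1] - full[0]) * 0.05
            cand = np.linspace(lo, hi, 31)
            inside = pos[(pos >= lo) & (pos <= hi)]
            if len(inside) > 60:
                inside = inside[:: len(inside) // 60 + 1]
            cand = np.unique(np.concatenate([cand, inside]))
            for c in cand:
                lam, pi, ll, conv = _em_fixed_c(x, c, lam_b, pi_b)
                if ll > ll_b:
                    ll_b, lam_b, c_b, pi_b, conv_b = ll, lam, c, pi, conv
            full = np.sort(np.unique(np.concatenate([full, cand])))
        ll2, lam2, c_best, pi_best, conv = ll_b, lam_b, c_b, pi_b, conv_b
    bic2 = 3 * math.log(n) - 2 * ll2
    delta = bic2 - bic1
    return MixtureFit(n=n, lambda_m1=lam1, loglik_m1=ll1, bic_m1=bic1,
                      lambda_m2=lam2, c=c_best, pi=pi_best, loglik_m2=ll2,
                      bic_m2=bic2, delta_bic=delta, decision=classify(bic1, bic2),
                      converged=conv,
                      note="" if conv else "EM hit max iterations")


def classify(bic_m1: float, bic_m2: float) -> str:
    """The +-10 Delta-BIC step rule, Delta = BIC_M2 - BIC_M1."""
    delta = bic_m2 - bic_m1
    if delta > DELTA_BIC_BAND:
        return ILS_ONLY
    if delta < -DELTA_BIC_BAND:
        return ILS_PLUS
    return INDISTINGUISHABLE


def introgressed_fraction(fit: MixtureFit, topology_frequency: float) -> float:
    """(1 - pi) * genomic topology frequency; 0 by convention when the
    ILS-only model is preferred."""
    if fit.decision == ILS_ONLY or math.isnan(fit.pi):
        return 0.0
    return (1.0 - fit.pi) * topology_frequency


# ---------------------------------------------------------------------------
# the full per-triplet table


@dataclass
class TripletClassResult:
    triplet: tuple[str, str, str]
    pair: tuple[str, str]
    concordant: bool
    count: int
    frequency: float
    fit: MixtureFit | None
    fraction: float
    flag: str = ""


def run_quibl(trees: Sequence[GeneTree], species_tree: GeneTree,
              triplets: Sequence[tuple[str, str, str]] | None = None,
              min_n: int = DEFAULT_MIN_N, n_starts: int = DEFAULT_N_STARTS,
              seed: int = 0) -> tuple[list[TripletClassResult], dict]:
    """Mixture classification for every triplet and topology class.

    Returns the per-class table plus a summary with the counts of tested
    classes deciding ILS-only / ILS+introgression / indistinguishable
    and the total introgressed-locus fraction per triplet.
    """
    if not trees:
        return [], {"n_triplets": 0, "n_tested": 0, ILS_ONLY: 0,
                    ILS_PLUS: 0, INDISTINGUISHABLE: 0}
    species = sorted({species_tree.species_of(l)
                      for l in species_tree.leaf_labels()})
    if triplets is None:
        triplets = list(combinations(species, 3))
    rows: list[TripletClassResult] = []
    counts = {ILS_ONLY: 0, ILS_PLUS: 0, INDISTINGUISHABLE: 0}
    n_tested = 0
    for k, trip in enumerate(triplets):
        classes = triplet_branch_lengths(trees, trip, species_tree)
        total = sum(len(rec["lengths"]) for rec in classes.values())
        for key in sorted(classes):
            rec = classes[key]
            cnt = len(rec["lengths"])
            freq = cnt / total if total else 0.0
            if cnt == 0:
                rows.append(TripletClassResult(trip, rec["pair"],
                                               rec["concordant"], 0, 0.0,
                                               None, 0.0, flag="empty class"))
                continue
            fit = fit_mixture(rec["lengths"], n_starts=n_starts,
                              seed=seed + 31 * k, min_n=min_n)
            flag = fit.note
            if rec["concordant"]:
                # the concordant class's non-ILS component is the
                # speciation branch itself, never introgression
                frac = 0.0
                flag = (flag + "; " if flag else "") + \
                    "non-ILS component = speciation branch"
            else:
                frac = introgressed_fraction(fit, freq)
            rows.append(TripletClassResult(trip, rec["pair"],
                                           rec["concordant"], cnt, freq,
                                           fit, frac, flag=flag))
            if not rec["concordant"] and \
                    not fit.note.startswith("insufficient"):
                n_tested += 1
                counts[fit.decision] += 1
    summary = {"n_triplets": len(triplets), "n_tested": n_tested, **counts}
    return rows, summary
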