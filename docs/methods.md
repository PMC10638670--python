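# Methods

## The model

`phylodisc` works under the multispecies coalescent (MSC) on a species
network. The species history is a rooted, ultrametric tree whose branch
lengths are in coalescent units of 2N generations; each branch carries a
relative effective population size that rescales its local coalescent
rate. At most one hybrid edge is allowed: at a fixed time, the lineage
ancestral to a designated recipient clade follows a donor lineage with
inheritance probability γ, independently per locus. This is
hybrid-speciation semantics — an entire locus takes one parental path —
rather than per-lineage migration, which matches a scenario of one
ancient reticulation forming a clade and keeps every locus's genealogy a
plain MSC draw on one of two parental trees. Conditional on the path,
ancestry is simulated with msprime; with all relative sizes at 1, an
internal branch of length τ produces the textbook discordance
probability (2/3)e^(−τ), which the tests exploit as an exact oracle.

Mutations follow an infinite-sites model (one mutation per site, no
back-mutation) at a rate per site per coalescent unit, dropped on
branches proportionally to length. Polarising site patterns against the
outgroup is therefore exact up to mutations on the outgroup's own
branch, which the polariser removes by construction. Loci are tiled onto
a synthetic chromosome (locus i occupies [i·(L+gap), i·(L+gap)+L)), so
all the window machinery runs on realistic half-open coordinates.

## Key parameters and defaults

| parameter | default | meaning |
|---|---|---|
| branch lengths | — | coalescent units (2N generations) |
| relative N per branch | 1.0 | rescales local coalescent rate; user-visible, never hidden |
| γ | 0.5 (default scenario) | probability a locus follows the donor path |
| mutation rate | 0.01 /site/coal. unit | gives a few informative sites per kb on short branches |
| sites per locus | 2,000 | synthetic window span |
| informative-site minimum | 10 | windows below it are filtered, not inferred |
| ΔBIC band | ±10 | BIC_M2 − BIC_M1 > 10 → ILS-only; < −10 → ILS+introgression |
| consensus threshold | 0.30 | minimum split frequency to enter the network |
| F_d selection | top 5% | candidate introgressed windows |
| tract selection | top 1% | windows by summed above-threshold dosage |
| dosage threshold | 1.5 (strict >) | introgression sites from local-ancestry dosage |
| jackknife block | 1 Mb (library), 25 kb (synthetic pipeline) | scaled so ≥20 blocks exist; Z is flagged unreliable below 20 |
| bootstrap replicates | 500 | individual-level γ resampling |

The default synthetic scenario has three in-group clades of two species
each plus an outgroup, a 0.5-coalescent-unit internode at the conflicted
node (≈ 40% discordant loci from ILS alone) and a hybrid clade
receiving γ = 0.5 from the donor clade at 1.0 coalescent units, placed
so both parental paths share 0.5 units with their parent — balanced
divergences keep the γ estimator unbiased while the ILS level stays
high, the regime the whole analysis is about. The genome-scale analysis windows (200-kb trees, 20-kb
QuIBL windows with 400-kb gaps, 10-kb F_d, 100-kb heterozygosity)
remain the CLI defaults for real coordinates; the synthetic pipeline
sets one window per 2-kb locus, which exercises the same code paths at
desk scale. Because synthetic loci are unlinked by construction, the
gapped thinning used on real data to avoid recombination breakpoints is
unnecessary there and the pipeline defaults its gap to zero.

## Estimators and numerical choices

**Window trees.** Neighbor joining on Jukes–Cantor-corrected distances
between per-species majority-consensus sequences replaces a full ML
substitution-model fit. Downstream statistics consume window trees only
through topologies and internal branch lengths, which NJ recovers well
at these divergences; the dialect difference from GTR-based ML is
deliberate and documented here. Saturated distances (p ≥ 0.75) are
capped at 5 substitutions/site with the cap noted; within-species
dosage ties exclude the site from consensus for determinism. Tiny
negative NJ branch lengths are clamped to zero.

**Quartet scores and search.** Scores are exact enumerations over all
quartets around each branch (a seeded uniform sample above a 20,000
quartet budget). The species-tree search scores every unrooted topology
for ≤ 8 taxa against the gene-tree quartet tally; beyond 8, greedy
taxon insertion plus NNI hill-climbing, with lexicographic tie-breaks
on the canonical topology string so results are deterministic. The
per-branch "support" is a multinomial tail heuristic on q1's excess
over the better alternative — an intentionally simple stand-in for a
local posterior probability, and not numerically comparable to one.
Note the (1/3)e^(−τ) closed form for the alternatives holds on
caterpillar-like arrangements; a branch flanked by a sister cherry
multiplies in that pair's own non-coalescence probability, which the
test suite demonstrates.

**D and f statistics.** Pattern weights use population derived-allele
frequencies, ABBA = (1−p1)p2p3 and BABA = p1(1−p2)p3 after outgroup
polarisation. The jackknife is delete-one over contiguous
physical-position blocks with equal weights; Z is reported only with
≥ 2 blocks and flagged below 20. F_d uses the dynamic donor
max(p2, p3) per site; windows with non-positive denominator or negative
numerator are undefined (NaN) rather than clamped — this follows the
statistic's standard convention and deliberately affects tail
selection. Tail selection keeps ceil(f·n_defined) windows, ties broken
by genomic order. F_ST is Hudson's estimator as a ratio of averages;
negative values are retained.

**γ estimation.** For (P1, H, P2) with polarised frequencies, the three
informative rooted patterns are BBAA (P1,H share), ABBA (H,P2 share)
and BABA (P1,P2 share). Under locus-level path choice with equal
parental internal branches, E[ABBA] and E[BBAA] are linear in γ with a
common ILS baseline E[BABA], giving

    γ̂ = (ABBA − BABA) / ((ABBA − BABA) + (BBAA − BABA)).

This estimator is derived here from that linearity; it is not a
transcription of any published invariant set. Its assumptions matter:
unequal parental divergences bias γ̂ away from the true mixing
proportion (the swap symmetry γ̂ → 1−γ̂ under P1↔P2 is exact
regardless, and is unit-tested). Clade-level frequencies built from
structured populations are conservative — the default pipeline's
clade-level γ̂ ≈ 0.37 for a true 0.5 — while single-lineage triplets
with equal divergences recover γ within ±0.05. Significance is a
site-block bootstrap of γ̂ against the nearer of {0, 1} (the
no-hybridization endpoints), two-sided normal tail, Bonferroni across
triplets in scans; γ̂ is clamped to [0, 1] for reporting with the raw
value retained.

**Branch-length mixtures.** Each triplet topology class is fit with M1:
Exp(rate λ) and M2: π·Exp(λ) + (1−π)·[c + Exp(λ)], shared rate,
location c ≥ 0. The component families follow MSC theory — ILS
internal branches are exponential from zero, non-ILS branches
concentrate at a positive divergence offset — and are validated purely
by recovery tests. EM runs over (π, λ) with c profiled: a 13-point
quantile grid plus two zoom passes that also try the data values inside
the bracket, because the profile likelihood peaks exactly at an order
statistic of the shifted component. 10 random starts, logL tolerance
1e−8, 500 iterations max, all seed-controlled. BIC uses k = 1 vs 3.
The decision takes Δ = BIC_M2 − BIC_M1 with the ±10 band; this
resolution of the rule's direction makes "Δ > 10 → ILS-only" literally
true. For the concordant topology class the non-ILS component is the
speciation branch itself, so it never counts toward introgression; the
introgressed-locus fraction is (1−π) times the class's genomic
frequency, summed over discordant classes. Window trees carry
substitutions/site lengths whose resolution (≈ 1/sites-per-window) can
blur a small offset c — at the default synthetic scale most classes are
honestly "indistinguishable", while coalescent-unit gene trees give
sharp decisions; a substitutions→coalescent conversion is deliberately
not attempted.

**Local ancestry.** A two-state-per-haplotype HMM with the diploid
chain as the product of two exchangeable haplotype chains (3 states = 0,
1, 2 source-2 haplotypes). Haplotypes switch ancestry at rate
g·r per bp and redraw the source from the prior; emissions are binomial
mixtures of panel allele frequencies with 0.5 pseudocounts. The
forward–backward recursion is written directly because both transitions
(physical distance) and emissions (panel frequencies) vary per site.
Posterior mean dosages from runs with different g values are averaged
(three-value scheme); post-processing rules are fixed: strict > 1.5
calls, per-window sums of above-threshold dosages, top 1% tracts, and
intersection with the F_d top 5% as final candidates. A degenerate
all-zero selection is returned flagged rather than suppressed. The
dosage rule detects homozygous-source regions; heterozygous-ancestry
tracts (dosage ≈ 1) are invisible to it by design.

**Partitioned trees.** The final candidate introgressed regions are the
intersection of the F_d top tail with the ancestry tracts; on a
desk-scale window grid that intersection can shrink to a window or two,
so below 3 windows the pipeline partitions on the union of the two
selections instead (the rule used is recorded in the report). The
hybrid clade's attachment in each partition tree is decided by a
majority vote over hybrid leaves — each votes for the parental clade
present in the smallest containing clade — which is robust to the
hybrid not being monophyletic in a noisy tree. One caveat is inherent
to the design and worth stating plainly: conditioning on high-F_d
windows enriches for ILS genealogies that mimic introgression, so the
introgressed-region tree tends to attach the hybrid to the donor even
under pure ILS. The partition check corroborates a hybridization call;
the detection itself rests on the γ scan.

**Trio enumeration.** Trios are ordered ((M1, M2), M3) by the reference
topology, cherries identified topologically (minimal MRCA clade size)
so length-free topologies order correctly; unresolved triples fall to
an alphabetical tie-break and are flagged. For n taxa the count is
C(n, 3) — 560 for 16 taxa.

## What the generator emulates — and what it does not

The synthetic scenario reproduces the statistical structure the
analysis assumes: 8–24 lineages, short internodes (high ILS), one
reticulation with γ near 0.5, window-structured coordinates, and an
outgroup basal to everything. It does not model recombination within a
locus, sequencing or genotyping error, missing data patterns,
selection, or repeat/mappability masking. Passing tests therefore
demonstrate that the estimators recover the truth under their own
model assumptions at desk scale; they do not certify robustness to the
artefacts of real resequencing data, and real-data window counts or
significance levels will differ.

## Seeding and reproducibility

One global seed fans out to per-stage seeds through a hash counter
(`stage_seed`), so any stage can be rerun independently and every
output is regenerable from config plus seed alone; the pipeline writes
a manifest with the config, its hash and the report. msprime seeds are
drawn from the stage RNG and kept below 2^31.

## Known limitations

- One hybrid edge; no multi-reticulation networks.
- The γ estimator's equal-parental-divergence assumption (bias
  otherwise) and its conservativeness on structured clades.
- NJ/JC window trees underestimate deep branch lengths relative to
  GTR ML; topology-level conclusions are unaffected at these scales.
- The quartet-support "support" value is a heuristic, not a posterior.
- partition_trees assumes a single synthetic chromosome per partition
  when re-using the window-tree engine.
- The D-statistic at the default 300-locus pipeline scale has limited
  power (|Z| ≈ 2–3 for a γ = 0.5 clade signal); the dedicated power
  analysis uses 1,000 loci where Z ≥ 3 is routine.
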