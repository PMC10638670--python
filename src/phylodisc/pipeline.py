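"""End-to-end orchestration of the discordance-attribution analysis.

``run_pipeline`` composes the stages on synthetic data: simulate gene
trees and genotypes under a species network -> window trees -> topology
table -> quartet-support species tree and consensus splits -> D
statistics and f-branch -> gamma scan for hybrid origin -> branch-length
mixture classification -> windowed F_d -> local-ancestry dosages and
tract calling -> candidate-region intersection -> trees from
introgressed vs non-introgressed partitions.

Every analysis threshold defaults to its standard value (informative
sites >= 10, Delta-BIC band +-10, consensus threshold 0.30, F_d top 5%,
tract top 1%, dosage threshold 1.5, 500 bootstrap replicates); all are
overridable.  One global seed fans out to per-stage seeds through a
counter so stages can be rerun independently and the whole report is
reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ancestry as anc
from . import hybdetect, io, quibl, sitepat, sptree, winphylo
from .simnet import (GenotypeMatrix, HybridEdge, SpeciesNetwork,
                     simulate_gene_trees, simulate_genotypes)
from .trees import GeneTree, canonical_topology, tree_from_newick

log = logging.getLogger("phylodisc")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

# default synthetic radiation: three in-group clades of two species each,
# short internodes (high ILS: ~40% discordant loci at the conflicted
# node), hybrid clade H receiving from the P2 clade with balanced shared
# branches (0.5 coalescent units on each parental path)
DEFAULT_NEWICK = ("((((H1:0.5,H2:0.5):0.5,(P1a:0.5,P1b:0.5):0.5):0.5,"
                  "(P2a:0.5,P2b:0.5):1.0):3.5,OUT:5.0);")
DEFAULT_CLADES = {
    "hybrid": ("H1", "H2"),
    "parent1": ("P1a", "P1b"),
    "parent2": ("P2a", "P2b"),
}


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end analysis.

    Window sizes are in bp of the synthetic coordinate system; on the
    default scenario one locus spans one window-tree window, so the
    window machinery and the locus structure line up by construction.
    """

    # species network
    newick: str = DEFAULT_NEWICK
    outgroup: str = "OUT"
    clades: dict = field(default_factory=lambda: dict(DEFAULT_CLADES))
    hybrid_recipient: tuple = ("H1", "H2")
    hybrid_donor: tuple = ("P2a", "P2b")
    hybrid_time: float = 1.0
    gamma: float = 0.5

    # simulation sizes
    n_loci: int = 300
    sites_per_locus: int = 2000
    mut_rate: float = 0.01
    locus_gap: int = 0

    # windows (bp of synthetic coordinates)
    gf_window_size: int = 2000
    quibl_window_gap: int = 0     # loci are unlinked; no thinning needed
    fd_window_size: int = 2000
    het_window_size: int = 10000

    # thresholds (standard defaults)
    min_informative: int = 10
    delta_bic_band: float = 10.0
    consensus_threshold: float = 0.30
    fd_top_fraction: float = 0.05
    tract_top_fraction: float = 0.01
    dosage_threshold: float = 1.5
    bootstrap_reps: int = 500
    # sized so the default synthetic genome (n_loci * sites_per_locus bp)
    # yields >= 20 jackknife blocks
    jackknife_block: int = 25_000
    alpha: float = 0.05

    # local ancestry
    ancestry_g: tuple = (5.0, 10.0, 15.0)
    recomb_rate: float = 1e-6

    quibl_min_n: int = 30
    seed: int = 0

    def network(self) -> SpeciesNetwork:
        hybrid = None
        if self.gamma > 0:
            hybrid = HybridEdge(recipient=self.hybrid_recipient,
                                donor=self.hybrid_donor,
                                time=self.hybrid_time, gamma=self.gamma)
        return SpeciesNetwork(newick=self.newick, outgroup=self.outgroup,
                              hybrid=hybrid)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clades"] = {k: list(v) for k, v in self.clades.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: int) -> int:
    """Counter-based per-stage seed derivation (independent reruns)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _clade_matrix(gm: GenotypeMatrix, clades: dict, outgroup: str
                  ) -> GenotypeMatrix:
    """Relabel individuals to clade-level populations for the gamma scan."""
    sp2clade = {}
    for clade, members in clades.items():
        for sp in members:
            sp2clade[sp] = clade
    pop_map = {ind: sp2clade.get(pop, pop)
               for ind, pop in gm.pop_map.items()}
    return GenotypeMatrix(chrom=gm.chrom, pos=gm.pos,
                          genotypes=gm.genotypes,
                          individuals=list(gm.individuals),
                          pop_map=pop_map, outgroup=outgroup)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full synthetic analysis; returns the structured report.

    With ``outdir``, per-stage tables are also written as TSV/BED plus a
    reproducibility manifest (config, per-stage seeds, config hash).
    Stage failures raise with the stage name; previously written outputs
    are preserved.
    """
    report: dict = {"config_hash": config.digest(), "stages": {}}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_names = []

    def stage(name):
        stage_names.append(name)
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)
        return stage_seed(config.seed, len(stage_names))

    try:
        # -- simulate -------------------------------------------------
        s = stage("simulate")
        net = config.network()
        trees = simulate_gene_trees(net, config.n_loci, seed=s)
        gm = simulate_genotypes(trees, config.sites_per_locus,
                                config.mut_rate, seed=stage_seed(s, 1),
                                gap=config.locus_gap)
        gm.outgroup = config.outgroup
        genome_len = int(gm.pos.max()) + 1 if gm.n_sites else 0
        donor_frac = float(np.mean([t.meta.get("path") == "donor"
                                    for t in trees]))
        report["stages"]["simulate"] = {
            "n_loci": config.n_loci, "n_sites": gm.n_sites,
            "donor_path_fraction": donor_frac}

        # -- window trees ---------------------------------------------
        stage("window_trees")
        windows = winphylo.make_windows({"chr1": genome_len},
                                        config.gf_window_size,
                                        gap=config.quibl_window_gap)
        wt = winphylo.infer_window_trees(gm, windows, config.outgroup,
                                         config.min_informative)
        window_trees = [t for _, t in wt if t is not None]
        report["stages"]["window_trees"] = {
            "n_windows": len(windows), "n_trees": len(window_trees),
            "n_filtered": len(wt) - len(window_trees)}

        # -- topology table -------------------------------------------
        stage("topologies")
        table = winphylo.tabulate_topologies(window_trees,
                                             outgroup=config.outgroup)
        report["stages"]["topologies"] = {
            "top2": table.top(2),
            "frequencies": dict(sorted(table.frequencies.items(),
                                       key=lambda kv: -kv[1])[:5])}

        # -- species tree ----------------------------------------------
        s = stage("species_tree")
        sp_est, supports = sptree.infer_species_tree(
            window_trees, outgroup=config.outgroup, seed=s)
        splits = sptree.consensus_splits(window_trees,
                                         config.consensus_threshold)
        report["stages"]["species_tree"] = {
            "topology": canonical_topology(sp_est, outgroup=config.outgroup),
            "quartet_scores": [
                {"branch": q.branch_id, "q1": q.q1, "q2": q.q2,
                 "q3": q.q3, "support": q.support} for q in supports],
            "n_consensus_splits": len(splits.splits)}

        # -- D statistics / f-branch -----------------------------------
        stage("dstats")
        pf = sitepat.polarize(gm)
        ingroup = [p for p in gm.populations() if p != config.outgroup]
        trios = sitepat.enumerate_trios(sp_est, ingroup)
        drows = []
        for (m1, m2, m3), flagged in trios:
            r = sitepat.patterson_d(pf, m1, m2, m3,
                                    block_size=config.jackknife_block)
            drows.append({"P1": m1, "P2": m2, "P3": m3, "D": r.d,
                          "Z": r.z, "n_blocks": r.n_blocks,
                          "flag": r.note})
        fb = sitepat.f_branch(sp_est, pf, ingroup)
        top_fb = sorted((c for c in fb if c.value is not None),
                        key=lambda c: -c.value)[:5]
        report["stages"]["dstats"] = {
            "n_trios": len(trios),
            "n_significant": sum(1 for r in drows
                                 if not r["flag"] and abs(r["Z"] or 0) >= 3),
            "fbranch_top": [{"branch": c.branch_id, "donor": c.donor,
                             "f": c.value} for c in top_fb]}

        # -- gamma scan -------------------------------------------------
        s = stage("gamma_scan")
        gm_clade = _clade_matrix(gm, config.clades, config.outgroup)
        pf_clade = sitepat.polarize(gm_clade)
        units = [c for c in gm_clade.populations() if c != config.outgroup]
        scan = hybdetect.scan_triplets(pf_clade, units, alpha=config.alpha,
                                       block_size=config.jackknife_block,
                                       seed=s)
        sig = [e for e in scan if e.verdict == "hybridization"]
        report["stages"]["gamma_scan"] = {
            "n_triplets": len(scan), "n_significant": len(sig),
            "results": [{"triplet": e.triplet, "gamma": e.gamma,
                         "z": e.z, "p": e.p_value, "verdict": e.verdict}
                        for e in scan]}

        # -- QuIBL-style mixture ----------------------------------------
        s = stage("quibl")
        reps = [members[0] for members in config.clades.values()]
        triplets = []
        cl = list(config.clades.values())
        for i in range(len(cl)):
            for j in range(i + 1, len(cl)):
                for k in range(j + 1, len(cl)):
                    for a in cl[i]:
                        for b in cl[j]:
                            for c in cl[k]:
                                triplets.append(tuple(sorted((a, b, c))))
        qrows, qsummary = quibl.run_quibl(window_trees, sp_est,
                                          triplets=triplets,
                                          min_n=config.quibl_min_n, seed=s)
        hyb_set = set(config.clades.get("hybrid", ()))
        hyb_introg = [r for r in qrows
                      if r.fit is not None and set(r.triplet) & hyb_set
                      and r.fit.decision == quibl.ILS_PLUS]
        per_triplet: dict = {}
        for r in qrows:
            per_triplet[r.triplet] = per_triplet.get(r.triplet, 0.0) + \
                r.fraction
        report["stages"]["quibl"] = {
            **qsummary,
            "hybrid_clade_introgression_classes": len(hyb_introg),
            "mean_introgressed_fraction": float(
                np.mean(list(per_triplet.values()))) if per_triplet else 0.0}

        # -- F_d windows -------------------------------------------------
        stage("fd")
        h_sp = config.clades["hybrid"][0]
        p1_sp = config.clades["parent1"][0]
        p2_sp = config.clades["parent2"][0]
        fd_wins = winphylo.make_windows({"chr1": genome_len},
                                        config.fd_window_size)
        # (((P1, H), donor P2), O): excess sharing of H with the donor
        fds = sitepat.fd_windows(pf, p1_sp, h_sp, p2_sp, fd_wins)
        fd_top = sitepat.top_fraction(fds, config.fd_top_fraction)
        report["stages"]["fd"] = {
            "n_windows": len(fds),
            "n_defined": sum(1 for s_ in fds if s_.defined),
            "n_top": len(fd_top)}

        # -- local ancestry ----------------------------------------------
        s = stage("ancestry")
        gm_cl = _clade_matrix(gm, config.clades, config.outgroup)
        tracks = anc.infer_dosage(gm_cl, "hybrid", "parent1", "parent2",
                                  g=list(config.ancestry_g),
                                  recomb_rate=config.recomb_rate,
                                  n_runs=len(config.ancestry_g), seed=s)
        tracts = anc.call_tracts(tracks, fd_wins,
                                 fraction=config.tract_top_fraction,
                                 threshold=config.dosage_threshold)
        candidates = anc.intersect_candidates(tracts, fd_top)
        report["stages"]["ancestry"] = {
            "n_tracks": len(tracks),
            "mean_dosage": float(np.mean([t.dosage.mean()
                                          for t in tracks])),
            "n_tract_windows": len(tracts.selected),
            "tracts_degenerate": tracts.degenerate,
            "n_candidate_regions": len(candidates)}

        # -- partitioned trees -------------------------------------------
        stage("partition_trees")
        # the intersection is the principled candidate set, but on a
        # desk-scale grid it can hold only a window or two; below a
        # minimum the union of the two selections is used instead so the
        # partition trees rest on enough variants (rule recorded)
        union = sorted({s_.window for s_ in tracts.selected} |
                       {s_.window for s_ in fd_top})
        if len(candidates) >= 3:
            regions, rule = candidates, "intersection"
        else:
            regions, rule = union, "union"
        partition = {"attempted": bool(regions), "region_rule": rule,
                     "n_regions": len(regions)}
        if regions:
            try:
                t_in, t_out = anc.partition_trees(gm, regions,
                                                  config.outgroup)
                p1_set = set(config.clades.get("parent1", ()))
                p2_set = set(config.clades.get("parent2", ()))
                att_in = _attachment(t_in, hyb_set, p1_set, p2_set)
                att_out = _attachment(t_out, hyb_set, p1_set, p2_set)
                partition.update({
                    "introgressed_topology":
                        canonical_topology(t_in, outgroup=config.outgroup),
                    "nonintrogressed_topology":
                        canonical_topology(t_out, outgroup=config.outgroup),
                    "hybrid_sister_introgressed":
                        _sister_clade(t_in, hyb_set, config.outgroup),
                    "hybrid_sister_nonintrogressed":
                        _sister_clade(t_out, hyb_set, config.outgroup),
                    "hybrid_attachment_introgressed": att_in,
                    "hybrid_attachment_nonintrogressed": att_out,
                })
                partition["positions_differ"] = (att_in != att_out)
            except ValueError as exc:
                partition["error"] = str(exc)
        report["stages"]["partition_trees"] = partition

        # -- verdict ------------------------------------------------------
        gamma_hit = [e for e in sig
                     if e.triplet[1] == "hybrid"]
        report["summary"] = {
            "hybrid_detected_by_gamma": bool(gamma_hit),
            "gamma_estimate": gamma_hit[0].gamma if gamma_hit else None,
            "partition_trees_differ":
                report["stages"]["partition_trees"].get("positions_differ"),
            "discordance_attribution":
                "ILS+hybridization" if gamma_hit else "ILS",
        }
    except Exception:
        log.error("pipeline failed in stage %r",
                  stage_names[-1] if stage_names else "init")
        raise

    report["elapsed_s"] = round(time.time() - t_start, 2)
    if out is not None:
        _write_outputs(out, config, report, gm, window_trees, drows,
                       fds, tracts)
    return report


def _attachment(tree: GeneTree, hybrid: set, clade_a: set, clade_b: set
                ) -> str | None:
    """Which parental clade the hybrid leaves attach to, by majority vote.

    Each hybrid leaf votes for the parental clade represented in the
    smallest clade of the tree containing that leaf and any parental
    leaf; robust to the hybrid clade not being monophyletic in a noisy
    tree.  Returns "parent1", "parent2", or None on a tie / no votes.
    """
    leafsets: dict[int, set] = {}
    votes = {"parent1": 0, "parent2": 0}
    nodes = list(tree.tree.postorder_node_iter())
    for node in nodes:
        if node.is_leaf():
            leafsets[id(node)] = {tree.species_of(node.taxon.label)}
        else:
            s: set = set()
            for ch in node.child_nodes():
                s |= leafsets[id(ch)]
            leafsets[id(node)] = s
    for h in hybrid:
        best = None
        for node in nodes:
            below = leafsets[id(node)]
            if h in below and (below & clade_a or below & clade_b):
                if best is None or len(below) < len(best):
                    best = below
        if best is None:
            continue
        a, b = bool(best & clade_a), bool(best & clade_b)
        if a and not b:
            votes["parent1"] += 1
        elif b and not a:
            votes["parent2"] += 1
    if votes["parent1"] > votes["parent2"]:
        return "parent1"
    if votes["parent2"] > votes["parent1"]:
        return "parent2"
    return None


def _sister_clade(tree: GeneTree, clade: set, outgroup: str):
    """Leaf set sister to the given clade in a rooted tree, as a sorted
    tuple (None when the clade is not monophyletic)."""
    from .trees import root_with_outgroup
    t = root_with_outgroup(tree, outgroup)
    for node in t.tree.postorder_node_iter():
        below = {t.species_of(l.taxon.label) for l in node.leaf_iter()}
        if below == clade:
            parent = node.parent_node
            if parent is None:
                return None
            sis = set()
            for sib in parent.child_nodes():
                if sib is not node:
                    sis |= {t.species_of(l.taxon.label)
                            for l in sib.leaf_iter()}
            return tuple(sorted(sis))
    return None


def _write_outputs(out: Path, config, report, gm, window_trees, drows,
                   fds, tracts):
    from .trees import write_newick_trees

    tag = report["config_hash"]
    io.write_vcf(gm, out / "genotypes.vcf")
    io.write_pop_map(gm.pop_map, out / "populations.tsv")
    write_newick_trees(window_trees, out / "window_trees.nwk")
    io.write_tsv(drows, out / "dstats.tsv", header_comment=f"config={tag}")
    io.write_window_stats(fds, out / "fd_windows.tsv",
                          header_comment=f"config={tag}")
    io.write_bed([s.window for s in tracts.selected], out / "tracts.bed")
    manifest = {"config": config.to_dict(), "config_hash": tag,
                "report": report}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
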