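"""File I/O: minimal VCF, population maps, BED, TSV and Newick lists.

All genomic intervals are 0-based half-open internally; VCF positions
(1-based) are converted at the boundary.  The VCF writer emits GT-only
biallelic SNV records; the reader (cyvcf2) skips multi-allelic records
with a logged count and treats any call containing a missing allele as
missing.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .simnet import GenotypeMatrix
from .sitepat import WindowStat
from .winphylo import WindowSpec

log = logging.getLogger("phylodisc")

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_pop_map",
    "read_pop_map",
    "write_bed",
    "write_window_stats",
    "write_tsv",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(gm.chrom.tolist()):
            length = int(gm.pos[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" +
                 "\t".join(gm.individuals) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_CODE[int(g)] for g in gm.genotypes[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i] + 1}\t.\tA\tT\t.\tPASS\t."
                     f"\tGT\t{gts}\n")


def read_vcf(path, pop_map: dict[str, str],
             outgroup: str | None = None) -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped (count logged); genotypes with any
    missing allele become -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, pos, rows = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        g = rec.genotype.array()[:, :2]
        dosage = np.where((g < 0).any(axis=1), -1, g.sum(axis=1))
        chroms.append(rec.CHROM)
        pos.append(rec.POS - 1)
        rows.append(dosage.astype(np.int8))
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    geno = np.vstack(rows) if rows else \
        np.zeros((0, len(individuals)), dtype=np.int8)
    return GenotypeMatrix(chrom=np.asarray(chroms), pos=np.asarray(pos),
                          genotypes=geno, individuals=individuals,
                          pop_map=dict(pop_map), outgroup=outgroup,
                          meta={"n_multiallelic_skipped": n_multi})


def write_pop_map(pop_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for ind, pop in pop_map.items():
            fh.write(f"{ind}\t{pop}\n")


def read_pop_map(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ind, pop = line.split("\t")[:2]
            out[ind] = pop
    return out


def write_bed(intervals: Iterable[WindowSpec], path,
              scores: Sequence[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(intervals):
            extra = "" if scores is None else f"\t{scores[i]:.6g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}{extra}\n")


def write_window_stats(stats: Sequence[WindowStat], path,
                       header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("chrom\tstart\tend\tstat\tvalue\tn_informative\n")
        for s in stats:
            fh.write(f"{s.window.chrom}\t{s.window.start}\t{s.window.end}"
                     f"\t{s.name}\t{s.value:.6g}\t{s.n_informative}\n")


def write_tsv(rows: Sequence[dict], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if not rows:
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in cols) + "\n")
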