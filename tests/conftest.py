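import numpy as np
import pytest

from phylodisc.simnet import (GenotypeMatrix, HybridEdge, SpeciesNetwork,
                              simulate_gene_trees)

TRIO_NEWICK = "(((P1:0.5,P2:0.5):0.5,P3:1.0):2.0,O:3.0);"
HYBRID_NEWICK = "(((P1:1.0,H:1.0):1.0,P2:2.0):2.0,O:4.0);"


@pytest.fixture(scope="session")
def trio_network():
    return SpeciesNetwork(newick=TRIO_NEWICK, outgroup="O")


@pytest.fixture(scope="session")
def hybrid_network():
    """Hybrid H with equal parental divergences (both internal branches 1)."""
    return SpeciesNetwork(
        newick=HYBRID_NEWICK, outgroup="O",
        hybrid=HybridEdge(recipient=("H",), donor=("P2",), time=1.0,
                          gamma=0.5))


@pytest.fixture(scope="session")
def trio_trees_tau1():
    """2,000 loci on a 3-taxon tree with a tau=1 internal branch."""
    net = SpeciesNetwork(newick="((A:1.0,B:1.0):1.0,C:2.0);")
    return simulate_gene_trees(net, 2000, seed=11)


def toy_matrix(genos, pops, chrom="chr1", pos=None, outgroup=None):
    """Build a small GenotypeMatrix from a row-per-site dosage list."""
    genos = np.asarray(genos, dtype=np.int8)
    individuals = list(pops)
    pos = np.arange(genos.shape[0]) if pos is None else np.asarray(pos)
    return GenotypeMatrix(chrom=np.full(genos.shape[0], chrom), pos=pos,
                          genotypes=genos, individuals=individuals,
                          pop_map=dict(pops), outgroup=outgroup)
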