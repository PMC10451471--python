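import numpy as np
import pytest

from introgscan import dstat, treeops
from introgscan.variant_filters import GenotypeCall, SiteRecord

# 9-taxon strongylocentrotid-style species tree: an M clade
# ((Mnud,Mfra),Pdep) and an S clade with Hpul sister to a pectinate
# Strongylocentrotus ladder.
SPECIES_TREE_9 = (
    "(((Mnud,Mfra),Pdep),"
    "(Hpul,(Spur,(Sint,(Spal,(Sdro,Sfra))))));"
)

# 4-taxon ultrametric tree in coalescent units; internal branch T=1
QUARTET_TREE = "(((P1:1,P2:1):1,P3:2):4,O:6);"


@pytest.fixture
def species_tree_9():
    return treeops.read_trees(SPECIES_TREE_9, rooted=True)[0]


@pytest.fixture
def quartet():
    return treeops.QuartetSpec("P1", "P2", "P3", "O")


def make_site(chrom="chr1", pos=100, ref="A", alts=("G",), qual=50.0,
              annotations=None, genotypes=None):
    if annotations is None:
        annotations = {"MQ": 60.0, "QD": 20.0, "FS": 1.0, "SOR": 1.0,
                       "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
    if genotypes is None:
        genotypes = [GenotypeCall((0, 1), gq=99, dp=30)]
    return SiteRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                      qual=qual, annotations=dict(annotations),
                      genotypes=list(genotypes))


def make_genotype_matrix(gt_rows, samples, pos=None, chrom="chr1"):
    """gt_rows: list of per-site lists of (a1, a2) tuples."""
    gt = np.array(gt_rows, dtype=np.int8)
    n = gt.shape[0]
    if pos is None:
        pos = np.arange(1, n + 1) * 10
    return dstat.GenotypeMatrix(
        chrom=np.array([chrom] * n), pos=np.asarray(pos),
        samples=list(samples), gt=gt,
    )
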