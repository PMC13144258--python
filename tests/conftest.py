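import numpy as np
import pytest

from herbiscan.gene_models import GeneModel, Strand
from herbiscan.variant_calls import AllelicStatus, GenotypeMatrix, NucleotidePolymorphism


@pytest.fixture
def forward_gene():
    """Two-exon forward gene: 5'UTR 100..110, CDS split 110..125 + 140..155,
    3'UTR 155..165, introns 125..140, flanks outside 100..165."""
    return GeneModel(
        gene_id="TOY.FWD", chrom="chrT", start=100, end=165, strand=Strand.forward,
        exons=[(100, 125), (140, 165)],
        cds=[(110, 125), (140, 155)],
        utr5=[(100, 110)], utr3=[(155, 165)],
        acronym="ToyFwd", flank_bp=50,
    )


@pytest.fixture
def reverse_gene():
    """Mirror-image reverse-strand gene with the same layout."""
    return GeneModel(
        gene_id="TOY.REV", chrom="chrT", start=100, end=165, strand=Strand.reverse,
        exons=[(100, 125), (140, 165)],
        cds=[(110, 125), (140, 155)],
        utr5=[(155, 165)], utr3=[(100, 110)],
        acronym="ToyRev", flank_bp=50,
    )


@pytest.fixture
def single_exon_gene():
    return GeneModel(
        gene_id="TOY.ONE", chrom="chrT", start=101, end=140, strand=Strand.forward,
        exons=[(101, 140)], cds=[(101, 110)],
        acronym="ToyOne", flank_bp=20,
    )


def make_matrix(samples, loci_specs, calls):
    """Build a GenotypeMatrix from compact specs.

    loci_specs: list of (chrom, pos, ref, alts, qd); calls: list of strings,
    one per sample, each with one status letter per locus ('.' = missing).
    """
    loci = [
        NucleotidePolymorphism(chrom, pos, ref, tuple(alts), qd=qd)
        for chrom, pos, ref, alts, qd in loci_specs
    ]
    grid = np.array([[c for c in row] for row in calls], dtype="<U1")
    return GenotypeMatrix(samples=list(samples), loci=loci, calls=grid)


@pytest.fixture
def matrix_factory():
    return make_matrix
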