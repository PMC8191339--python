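import numpy as np
import pytest
from hypothesis import settings

from isokit import Gene, GenomeAnnotation, GenomicInterval, TranscriptModel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_transcript(tid, chrom, strand, exon_pairs, gene_id=None, cds=()):
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
        gene_id=gene_id,
        cds=tuple(cds),
    )


@pytest.fixture
def toy_annotation():
    """Two multi-isoform genes on opposite strands plus a mono-exon gene.

    geneA (+, chr1): A.t1 exons (100,200),(300,400),(500,600);
                     A.t2 exons (100,200),(450,600)
    geneB (-, chr1): B.t1 exons (2000,2100),(2200,2300)
    geneC (+, chr2): C.t1 single exon (100,400)
    """
    a1 = make_transcript("A.t1", "chr1", "+", [(100, 200), (300, 400), (500, 600)], "geneA")
    a2 = make_transcript("A.t2", "chr1", "+", [(100, 200), (450, 600)], "geneA")
    b1 = make_transcript("B.t1", "chr1", "-", [(2000, 2100), (2200, 2300)], "geneB")
    c1 = make_transcript("C.t1", "chr2", "+", [(100, 400)], "geneC")
    return GenomeAnnotation(
        [
            Gene("geneA", "chr1", "+", [a1, a2], name="GENEA", biotype="protein_coding"),
            Gene("geneB", "chr1", "-", [b1], name="GENEB", biotype="protein_coding"),
            Gene("geneC", "chr2", "+", [c1], name="GENEC", biotype="lncRNA"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
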