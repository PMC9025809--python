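import pytest

from isoforge.core import (
    GeneLocus,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    source: str = "reference",
    gene_id: str | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        gene_id=gene_id,
        source=source,
    )


@pytest.fixture
def three_exon_gene() -> GeneLocus:
    """One + strand gene, one transcript, exons [100,200) [300,400) [500,600)."""
    t = make_transcript("T1", [(100, 200), (300, 400), (500, 600)], gene_id="G1")
    return GeneLocus("G1", [t])


@pytest.fixture
def small_annotation(three_exon_gene) -> GenomeAnnotation:
    t2 = make_transcript(
        "T2", [(10_000, 10_150), (10_400, 10_600)], strand="-", gene_id="G2"
    )
    ann = GenomeAnnotation([three_exon_gene, GeneLocus("G2", [t2])])
    ann.chromosomes["chr1"] = 50_000
    return ann
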