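"""Stranded genomic intervals, exon-chain transcript models and GFF3/BED12 I/O.

All coordinates are held internally as 0-based half-open intervals; GFF3
readers and writers convert to and from the 1-based inclusive dialect.
Strand is always ``+`` or ``-`` — unstranded records are rejected because
every downstream rule (overlap, splice-chain identity, promoter windows)
is strand-conditional.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneLocus",
    "GenomeAnnotation",
    "OverlapReport",
    "GffParseError",
    "read_gff",
    "write_gff",
    "read_bed12",
    "exonic_overlap",
]

STRANDS = ("+", "-")


class GffParseError(ValueError):
    """Raised for malformed GFF3/BED input, naming the offending record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """An exon chain on one strand: the unit classified as known or novel.

    Exons are sorted, pairwise disjoint intervals on a single chromosome
    and strand; the intron chain is the ordered list of gaps between
    consecutive exons (empty for mono-exonic transcripts).
    """

    transcript_id: str
    exons: list[GenomicInterval]
    gene_id: str | None = None
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    source: str = "reference"  # "reference" or "isoseq"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.chrom != chrom or nxt.strand != strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons span chrom/strand"
                )
            if nxt.start < prev.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def location(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def intron_chain(self) -> list[tuple[int, int]]:
        """Ordered (donor-side, acceptor-side) coordinate gaps between exons."""
        return [
            (prev.end, nxt.start) for prev, nxt in zip(self.exons, self.exons[1:])
        ]

    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' terminus (strand-aware)."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    def five_prime_end(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end


@dataclass
class GeneLocus:
    gene_id: str
    transcripts: list[TranscriptModel]
    status: str = "known"  # "known" or "novel"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"locus {self.gene_id}: needs >= 1 transcript")
        chrom = self.transcripts[0].chrom
        strand = self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom or t.strand != strand:
                raise ValueError(
                    f"locus {self.gene_id}: transcripts on mixed chrom/strand"
                )
            t.gene_id = self.gene_id

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.location.start for t in self.transcripts)
        end = max(t.location.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def reference_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.source == "reference"]


class GenomeAnnotation:
    """A collection of gene loci keyed by gene_id plus a chromosome registry."""

    def __init__(
        self,
        loci: Iterable[GeneLocus] = (),
        chromosomes: dict[str, int] | None = None,
    ):
        self.loci: dict[str, GeneLocus] = {}
        self.chromosomes: dict[str, int] = dict(chromosomes or {})
        for locus in loci:
            self.add_locus(locus)

    def add_locus(self, locus: GeneLocus) -> None:
        if locus.gene_id in self.loci:
            raise ValueError(f"duplicate gene_id {locus.gene_id}")
        seen = self.transcript_ids()
        for t in locus.transcripts:
            if t.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        if locus.chrom not in self.chromosomes:
            self.chromosomes[locus.chrom] = 0
        self.chromosomes[locus.chrom] = max(
            self.chromosomes[locus.chrom], locus.span.end
        )
        self.loci[locus.gene_id] = locus

    def transcript_ids(self) -> set[str]:
        return {
            t.transcript_id for loc in self.loci.values() for t in loc.transcripts
        }

    def transcripts(self) -> Iterator[TranscriptModel]:
        for locus in self.loci.values():
            yield from locus.transcripts

    def n_loci(self) -> int:
        return len(self.loci)

    def n_transcripts(self) -> int:
        return sum(len(loc.transcripts) for loc in self.loci.values())

    def intron_universe(self) -> set[tuple[str, str, int, int]]:
        """All (chrom, strand, donor, acceptor) introns of any transcript."""
        universe: set[tuple[str, str, int, int]] = set()
        for t in self.transcripts():
            for d, a in t.intron_chain():
                universe.add((t.chrom, t.strand, d, a))
        return universe

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return _annotation_state(self) == _annotation_state(other)


def _annotation_state(ann: GenomeAnnotation):
    return {
        gid: (
            loc.status,
            tuple(
                (
                    t.transcript_id,
                    t.source,
                    tuple((e.chrom, e.start, e.end, e.strand) for e in t.exons),
                    tuple((u.start, u.end) for u in t.utr5),
                    tuple((u.start, u.end) for u in t.utr3),
                )
                for t in sorted(loc.transcripts, key=lambda t: t.transcript_id)
            ),
        )
        for gid, loc in ann.loci.items()
    }


# ---------------------------------------------------------------------------
# exonic overlap


@dataclass(frozen=True)
class OverlapReport:
    shared_bases: int
    fraction_of_a: float
    fraction_of_b: float
    fraction_of_shorter: float


def _merge_intervals(ivals: list[GenomicInterval]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    pts = sorted((iv.start, iv.end) for iv in ivals)
    merged = [list(pts[0])]
    for s, e in pts[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _union_intersection_size(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    shared = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            shared += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return shared


def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> OverlapReport:
    """Shared exonic bases between two models and the derived fractions.

    Models on different chromosomes or strands share zero bases. Fractions
    divide by each model's exonic length (sum of exon sizes), and
    ``fraction_of_shorter`` by the smaller of the two — the quantity the
    20%-overlap distinctness rule is evaluated on.
    """
    len_a = a.exonic_length
    len_b = b.exonic_length
    if a.chrom != b.chrom or a.strand != b.strand:
        shared = 0
    else:
        shared = _union_intersection_size(
            _merge_intervals(a.exons), _merge_intervals(b.exons)
        )
    return OverlapReport(
        shared_bases=shared,
        fraction_of_a=shared / len_a,
        fraction_of_b=shared / len_b,
        fraction_of_shorter=shared / min(len_a, len_b),
    )


# ---------------------------------------------------------------------------
# GFF3 I/O

_GFF_HEADER = "##gff-version 3"


def read_gff(path: str | os.PathLike) -> GenomeAnnotation:
    """Read a GFF3 gene/mRNA/exon (+UTR) hierarchy into a GenomeAnnotation.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    internal 0-based half-open. Parent/child links are resolved via the
    ID/Parent attributes using gffutils. Unstranded features are rejected.
    """
    _prevalidate_gff(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    loci: list[GeneLocus] = []
    chrom_lengths: dict[str, int] = {}
    for line in open(path):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                chrom_lengths[parts[1]] = int(parts[3])
    for gene in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
                for ex in db.children(mrna, featuretype="exon", level=1)
            ]
            utr5 = [
                GenomicInterval(u.seqid, u.start - 1, u.end, u.strand)
                for u in db.children(mrna, featuretype="five_prime_UTR", level=1)
            ]
            utr3 = [
                GenomicInterval(u.seqid, u.start - 1, u.end, u.strand)
                for u in db.children(mrna, featuretype="three_prime_UTR", level=1)
            ]
            if not exons:
                raise GffParseError(
                    f"transcript {mrna.id} has no exon children"
                )
            source = (
                mrna.attributes["model_source"][0]
                if "model_source" in mrna.attributes
                else "reference"
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    exons=exons,
                    gene_id=gene.id,
                    utr5=sorted(utr5, key=lambda u: u.start),
                    utr3=sorted(utr3, key=lambda u: u.start),
                    source=source,
                )
            )
        if not transcripts:
            raise GffParseError(f"gene {gene.id} has no mRNA children")
        status = (
            gene.attributes["locus_status"][0]
            if "locus_status" in gene.attributes
            else "known"
        )
        loci.append(GeneLocus(gene.id, transcripts, status=status))
    ann = GenomeAnnotation(loci)
    for chrom, length in chrom_lengths.items():
        ann.chromosomes[chrom] = max(ann.chromosomes.get(chrom, 0), length)
    return ann


def _prevalidate_gff(path: str | os.PathLike) -> None:
    """Line-level checks that produce errors naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"line {lineno}: expected 9 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GffParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise GffParseError(
                    f"line {lineno}: end < start ({end} < {start}): "
                    f"{line.strip()}"
                )
            if fields[2] in ("mRNA", "transcript", "exon", "gene",
                             "five_prime_UTR", "three_prime_UTR") \
                    and fields[6] not in STRANDS:
                raise GffParseError(
                    f"line {lineno}: unknown strand {fields[6]!r} "
                    "(only '+'/'-' accepted)"
                )


def write_gff(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write GFF3 (1-based inclusive), byte-deterministic for a fixed input.

    Records are ordered by chromosome (registry order), then locus start,
    then the gene > mRNA > exon > UTR hierarchy.
    """
    lines = [_GFF_HEADER]
    for chrom in annotation.chromosomes:
        length = annotation.chromosomes[chrom]
        if length > 0:
            lines.append(f"##sequence-region {chrom} 1 {length}")
    by_chrom: dict[str, list[GeneLocus]] = {c: [] for c in annotation.chromosomes}
    for locus in annotation.loci.values():
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in by_chrom:
        for locus in sorted(
            by_chrom[chrom], key=lambda L: (L.span.start, L.gene_id)
        ):
            span = locus.span
            lines.append(
                "\t".join(
                    [
                        chrom, "isoforge", "gene",
                        str(span.start + 1), str(span.end), ".",
                        locus.strand, ".",
                        f"ID={locus.gene_id};locus_status={locus.status}",
                    ]
                )
            )
            for t in sorted(
                locus.transcripts,
                key=lambda t: (t.location.start, t.transcript_id),
            ):
                loc = t.location
                lines.append(
                    "\t".join(
                        [
                            chrom, "isoforge", "mRNA",
                            str(loc.start + 1), str(loc.end), ".",
                            t.strand, ".",
                            f"ID={t.transcript_id};Parent={locus.gene_id};"
                            f"model_source={t.source}",
                        ]
                    )
                )
                for i, e in enumerate(t.exons, start=1):
                    lines.append(
                        "\t".join(
                            [
                                chrom, "isoforge", "exon",
                                str(e.start + 1), str(e.end), ".",
                                t.strand, ".",
                                f"ID={t.transcript_id}.exon{i};"
                                f"Parent={t.transcript_id}",
                            ]
                        )
                    )
                for kind, utrs in (
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for i, u in enumerate(utrs, start=1):
                        lines.append(
                            "\t".join(
                                [
                                    chrom, "isoforge", kind,
                                    str(u.start + 1), str(u.end), ".",
                                    t.strand, ".",
                                    f"ID={t.transcript_id}.{kind}{i};"
                                    f"Parent={t.transcript_id}",
                                ]
                            )
                        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def annotation_to_gff_string(annotation: GenomeAnnotation) -> str:
    with tempfile.NamedTemporaryFile("r", suffix=".gff3", delete=False) as tmp:
        name = tmp.name
    try:
        write_gff(annotation, name)
        with open(name) as fh:
            return fh.read()
    finally:
        os.unlink(name)


# ---------------------------------------------------------------------------
# BED12


def read_bed12(path: str | os.PathLike, source: str = "isoseq") -> list[TranscriptModel]:
    """Read spliced alignments from BED12, expanding blocks to exon chains."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise GffParseError(f"line {lineno}: BED12 needs 12 columns")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in STRANDS:
                raise GffParseError(
                    f"line {lineno}: unknown strand {strand!r}"
                )
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(f[9]):
                raise GffParseError(
                    f"line {lineno}: blockCount does not match block lists"
                )
            exons = [
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            models.append(
                TranscriptModel(transcript_id=name, exons=exons, source=source)
            )
    return models


def write_bed12(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    lines = []
    for t in models:
        loc = t.location
        sizes = ",".join(str(len(e)) for e in t.exons)
        starts = ",".join(str(e.start - loc.start) for e in t.exons)
        lines.append(
            "\t".join(
                [
                    t.chrom, str(loc.start), str(loc.end), t.transcript_id,
                    "0", t.strand, str(loc.start), str(loc.end), "0",
                    str(len(t.exons)), sizes, starts,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
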