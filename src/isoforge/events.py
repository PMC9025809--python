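"""Pairwise alternative-splicing event classification between isoforms.

Events are local structural differences between two exon chains of the
same locus, restricted to the genomic span both models share so that mere
end-length differences are never called as splicing. Five canonical types
are recognised: exon skipping, intron retention, alternative 5'/3' splice
site, and mutually exclusive exons. Alternative first/last exons and
compound structures outside this taxonomy are not classified.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GeneLocus, GenomicInterval, TranscriptModel

__all__ = ["ASEvent", "pairwise_events", "locus_events", "EVENT_TYPES"]

EVENT_TYPES = (
    "exon_skipping",
    "intron_retention",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive",
)


@dataclass(frozen=True)
class ASEvent:
    event_type: str
    gene_id: str | None
    variant_region: GenomicInterval
    isoform_pair: tuple[str, str]

    def dedup_key(self) -> tuple:
        return (
            self.event_type,
            self.variant_region.chrom,
            self.variant_region.start,
            self.variant_region.end,
            self.variant_region.strand,
        )


def _shared_span(a: TranscriptModel, b: TranscriptModel) -> tuple[int, int] | None:
    lo = max(a.location.start, b.location.start)
    hi = min(a.location.end, b.location.end)
    return (lo, hi) if lo < hi else None


def pairwise_events(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Classify the AS events distinguishing two isoform models.

    Rules, evaluated inside the span shared by both models:

    * exon_skipping — an intron of one model strictly contains a full exon
      of the other, and both of that intron's splice sites are splice
      sites of the other model (one event per skipped exon, variant region
      = the skipped exon).
    * intron_retention — an exon of one model fully contains an intron of
      the other together with flanking exonic sequence on both sides
      (variant region = the retained intron).
    * alt_5ss / alt_3ss — an intron from each model shares exactly one
      boundary, and the interval between the two alternative boundaries
      contains no complete exon of either model (which would make the
      difference a skip or mutually-exclusive structure instead). Which
      label applies follows transcription direction: a changed left
      boundary is donor-side (5') on '+' and acceptor-side (3') on '-'.
    * mutually_exclusive — internal exons, one per model, non-overlapping,
      framed by flanking introns whose outer splice sites coincide across
      the models (variant region = span of the two exclusive exons).

    Identical models yield no events. The result is symmetric in the two
    arguments up to the order recorded in ``isoform_pair``.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError(
            "pairwise_events requires models on the same chromosome and strand"
        )
    span = _shared_span(a, b)
    if span is None:
        return []
    lo, hi = span
    chrom, strand = a.chrom, a.strand
    pair = (a.transcript_id, b.transcript_id)
    gene_id = a.gene_id or b.gene_id
    events: dict[tuple, ASEvent] = {}

    def emit(etype: str, start: int, end: int) -> None:
        ev = ASEvent(
            etype, gene_id, GenomicInterval(chrom, start, end, strand), pair
        )
        events.setdefault(ev.dedup_key(), ev)

    ia = a.intron_chain()
    ib = b.intron_chain()
    sites_a = {p for d, ac in ia for p in (d, ac)}
    sites_b = {p for d, ac in ib for p in (d, ac)}
    all_exons = list(a.exons) + list(b.exons)

    def region_holds_full_exon(start: int, end: int) -> bool:
        return any(start <= e.start and e.end <= end for e in all_exons)

    # --- exon skipping -----------------------------------------------------
    for introns, other, other_sites in ((ia, b, sites_b), (ib, a, sites_a)):
        for d, ac in introns:
            if not (lo <= d and ac <= hi):
                continue
            if d in other_sites and ac in other_sites:
                for e in other.exons:
                    if d < e.start and e.end < ac:
                        emit("exon_skipping", e.start, e.end)

    # --- intron retention --------------------------------------------------
    for introns, other in ((ia, b), (ib, a)):
        for d, ac in introns:
            if not (lo <= d and ac <= hi):
                continue
            for e in other.exons:
                # exon spills over both intron boundaries -> covers the
                # intron plus parts of its flanking exons
                if e.start < d and ac < e.end:
                    emit("intron_retention", d, ac)

    # --- mutually exclusive exons ------------------------------------------
    for i, ea in enumerate(a.exons[1:-1], start=1):
        for j, eb in enumerate(b.exons[1:-1], start=1):
            if ea.overlaps(eb):
                continue
            dl_a, al_a = ia[i - 1]
            dr_a, ar_a = ia[i]
            dl_b, al_b = ib[j - 1]
            dr_b, ar_b = ib[j]
            if dl_a == dl_b and ar_a == ar_b and lo <= dl_a and ar_a <= hi:
                emit(
                    "mutually_exclusive",
                    min(ea.start, eb.start),
                    max(ea.end, eb.end),
                )

    # --- alternative 5'/3' splice sites ------------------------------------
    for d1, a1 in ia:
        if not (lo <= d1 and a1 <= hi):
            continue
        for d2, a2 in ib:
            if not (lo <= d2 and a2 <= hi):
                continue
            if d1 == d2 and a1 != a2:
                r0, r1 = min(a1, a2), max(a1, a2)
                if not region_holds_full_exon(r0, r1):
                    etype = "alt_3ss" if strand == "+" else "alt_5ss"
                    emit(etype, r0, r1)
            elif a1 == a2 and d1 != d2:
                r0, r1 = min(d1, d2), max(d1, d2)
                if not region_holds_full_exon(r0, r1):
                    etype = "alt_5ss" if strand == "+" else "alt_3ss"
                    emit(etype, r0, r1)

    return sorted(
        events.values(),
        key=lambda ev: (
            ev.variant_region.start,
            ev.variant_region.end,
            ev.event_type,
        ),
    )


def locus_events(locus: GeneLocus) -> tuple[list[ASEvent], int]:
    """Deduplicated union of pairwise events over all isoform pairs.

    Events with the same (type, variant region) found in different isoform
    pairs are counted once, matching the convention of genome-wide AS-event
    totals; the exemplar pair retained is the first in sorted id order.
    """
    transcripts = sorted(locus.transcripts, key=lambda t: t.transcript_id)
    seen: dict[tuple, ASEvent] = {}
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            for ev in pairwise_events(transcripts[i], transcripts[j]):
                seen.setdefault(ev.dedup_key(), ev)
    dedup = sorted(
        seen.values(),
        key=lambda ev: (
            ev.variant_region.chrom,
            ev.variant_region.start,
            ev.variant_region.end,
            ev.event_type,
        ),
    )
    return dedup, len(dedup)
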