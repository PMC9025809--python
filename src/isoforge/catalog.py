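"""Building an updated annotation from long-read full-length isoform candidates.

The pipeline mirrors the standard Iso-seq annotation-update workflow:

1. **retain** candidates by any of four criteria — multi-read support,
   single-read high alignment identity, full short-read junction support,
   or full containment of the splice chain in the reference intron set;
2. **collapse** redundant retained candidates (single-linkage at >= 20%
   exonic overlap of the shorter model, same strand);
3. **assign** representatives to known gene loci (>= 20% rule) or group the
   leftovers into novel loci;
4. **classify** each representative as a known isoform or a novel one
   (new intron, new exonic region, changed 3' end, or novel locus);
5. **merge** novel records into the reference to produce the updated
   annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    GeneLocus,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    _merge_intervals,
    _union_intersection_size,
    exonic_overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FLNCIsoformCandidate",
    "JunctionSet",
    "RetentionDecision",
    "IsoformStatus",
    "retain_candidates",
    "collapse_redundant",
    "assign_loci",
    "classify_isoform_status",
    "merge_annotation",
    "update_annotation",
]

CRITERIA = (
    "C1_multiread",
    "C2_single_read_high_pid",
    "C3_junctions_supported",
    "C4_events_annotated",
)


@dataclass
class FLNCIsoformCandidate:
    """A spliced-aligned isoform candidate with FLNC read support and PID."""

    candidate_id: str
    model: TranscriptModel
    flnc_read_count: int
    percent_identity: float

    def __post_init__(self) -> None:
        if self.flnc_read_count < 1:
            raise ValueError(
                f"{self.candidate_id}: flnc_read_count must be >= 1"
            )
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"{self.candidate_id}: percent_identity must be in [0, 100]"
            )


class JunctionSet:
    """A set of introns (chrom, strand, donor, acceptor), 0-based half-open."""

    def __init__(self, introns: set[tuple[str, str, int, int]] | None = None):
        self.introns: set[tuple[str, str, int, int]] = set()
        for j in introns or ():
            self.add(j)

    def add(self, intron: tuple[str, str, int, int]) -> None:
        chrom, strand, donor, acceptor = intron
        if donor >= acceptor:
            raise ValueError(f"intron {intron}: donor must precede acceptor")
        self.introns.add((chrom, strand, donor, acceptor))

    def __contains__(self, intron: tuple[str, str, int, int]) -> bool:
        return intron in self.introns

    def __len__(self) -> int:
        return len(self.introns)

    def supports(self, model: TranscriptModel) -> bool:
        """True iff every intron of the model is in the set (vacuous for
        mono-exonic models, which have no junctions to support)."""
        return all(
            (model.chrom, model.strand, d, a) in self.introns
            for d, a in model.intron_chain()
        )

    @classmethod
    def read_bed(cls, path: str) -> "JunctionSet":
        js = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                js.add((f[0], f[5], int(f[1]), int(f[2])))
        return js

    def write_bed(self, path: str) -> None:
        lines = [
            "\t".join([c, str(d), str(a), f"jx{i}", "0", s])
            for i, (c, s, d, a) in enumerate(sorted(self.introns))
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class RetentionDecision:
    candidate_id: str
    kept: bool
    criteria_met: frozenset[str]

    def __post_init__(self) -> None:
        if self.kept != bool(self.criteria_met):
            raise ValueError("kept must equal non-emptiness of criteria_met")


@dataclass
class IsoformStatus:
    transcript_id: str
    status: str  # "known" | "novel"
    reason: str  # matches_reference | new_intron | new_exon |
    #              changed_3prime_end | novel_locus

    def __post_init__(self) -> None:
        if self.status == "known" and self.reason != "matches_reference":
            raise ValueError("known isoforms must have reason matches_reference")


# ---------------------------------------------------------------------------
# 1. retention


def retain_candidates(
    candidates: list[FLNCIsoformCandidate],
    junctions: JunctionSet,
    reference: GenomeAnnotation,
    pid_threshold: float = 99.0,
) -> list[RetentionDecision]:
    """Evaluate each candidate against the four keep-criteria (OR).

    C1: supported by >= 2 FLNC reads.
    C2: a single FLNC read with percent identity above ``pid_threshold``.
    C3: every splice junction confirmed by the short-read junction set.
    C4: every intron present in the reference annotation's intron universe
        (splice structure fully annotated).
    """
    if not (0.0 <= pid_threshold <= 100.0):
        raise ValueError("pid_threshold must be in [0, 100]")
    universe = reference.intron_universe()
    decisions = []
    for cand in candidates:
        met = set()
        if cand.flnc_read_count >= 2:
            met.add("C1_multiread")
        if cand.flnc_read_count == 1 and cand.percent_identity > pid_threshold:
            met.add("C2_single_read_high_pid")
        if junctions.supports(cand.model):
            met.add("C3_junctions_supported")
        if all(
            (cand.model.chrom, cand.model.strand, d, a) in universe
            for d, a in cand.model.intron_chain()
        ):
            met.add("C4_events_annotated")
        decisions.append(
            RetentionDecision(cand.candidate_id, bool(met), frozenset(met))
        )
    return decisions


# ---------------------------------------------------------------------------
# 2. collapse


def _linked(a: FLNCIsoformCandidate, b: FLNCIsoformCandidate,
            threshold: float = 0.20) -> bool:
    if a.model.chrom != b.model.chrom or a.model.strand != b.model.strand:
        return False
    return exonic_overlap(a.model, b.model).fraction_of_shorter >= threshold


def collapse_redundant(
    candidates: list[FLNCIsoformCandidate],
    overlap_threshold: float = 0.20,
) -> tuple[list[FLNCIsoformCandidate], dict[str, str]]:
    """Single-linkage collapse of retained candidates.

    Two candidates link when they share at least ``overlap_threshold`` of
    the shorter model's exonic bases on the same strand; candidates below
    that are distinct isoforms. Returns one representative per cluster
    (most FLNC reads, then larger exonic length, then smallest id; its
    read count becomes the cluster sum) and a candidate_id -> representative
    membership map.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # sort by position to limit pair tests to overlapping spans
    order = sorted(
        range(n),
        key=lambda i: (
            candidates[i].model.chrom,
            candidates[i].model.strand,
            candidates[i].model.location.start,
        ),
    )
    active: list[int] = []
    for idx in order:
        ci = candidates[idx]
        active = [
            j for j in active
            if candidates[j].model.chrom == ci.model.chrom
            and candidates[j].model.strand == ci.model.strand
            and candidates[j].model.location.end > ci.model.location.start
        ]
        for j in active:
            if _linked(ci, candidates[j], overlap_threshold):
                ri, rj = find(idx), find(j)
                if ri != rj:
                    parent[ri] = rj
        active.append(idx)

    clusters: dict[int, list[FLNCIsoformCandidate]] = {}
    for i, cand in enumerate(candidates):
        clusters.setdefault(find(i), []).append(cand)

    representatives: list[FLNCIsoformCandidate] = []
    membership: dict[str, str] = {}
    for members in clusters.values():
        rep = min(
            members,
            key=lambda c: (
                -c.flnc_read_count,
                -c.model.exonic_length,
                c.candidate_id,
            ),
        )
        total = sum(c.flnc_read_count for c in members)
        rep_out = FLNCIsoformCandidate(
            candidate_id=rep.candidate_id,
            model=rep.model,
            flnc_read_count=total,
            percent_identity=rep.percent_identity,
        )
        representatives.append(rep_out)
        for c in members:
            membership[c.candidate_id] = rep.candidate_id
    representatives.sort(
        key=lambda c: (c.model.chrom, c.model.location.start, c.candidate_id)
    )
    return representatives, membership


# ---------------------------------------------------------------------------
# 3. locus assignment


def _gene_exon_union(locus: GeneLocus) -> list[tuple[int, int]]:
    exons = [e for t in locus.transcripts for e in t.exons]
    return _merge_intervals(exons)


def _candidate_gene_overlap(
    cand: FLNCIsoformCandidate, locus: GeneLocus
) -> tuple[int, float]:
    """Shared exonic bases and fraction-of-shorter vs a gene's exon union."""
    if cand.model.chrom != locus.chrom or cand.model.strand != locus.strand:
        return 0, 0.0
    cand_union = _merge_intervals(cand.model.exons)
    gene_union = _gene_exon_union(locus)
    shared = _union_intersection_size(cand_union, gene_union)
    gene_len = sum(e - s for s, e in gene_union)
    shorter = min(cand.model.exonic_length, gene_len)
    return shared, shared / shorter


def assign_loci(
    representatives: list[FLNCIsoformCandidate],
    reference: GenomeAnnotation,
    overlap_threshold: float = 0.20,
) -> tuple[dict[str, str], list[GeneLocus]]:
    """Assign each representative to a known gene or a new novel locus.

    A representative joins the known gene with the largest
    fraction-of-shorter exonic overlap when that fraction reaches the
    threshold (ties: more shared bases, then lexicographic gene_id).
    Unassigned representatives are single-linkage clustered among
    themselves by the same rule into novel loci named ``NG.<chrom>.<k>``
    with ``k`` numbered 1-based by leftmost start per chromosome.
    """
    assignment: dict[str, str] = {}
    unassigned: list[FLNCIsoformCandidate] = []
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in reference.loci.values():
        by_chrom.setdefault((locus.chrom, locus.strand), []).append(locus)

    for cand in representatives:
        best: tuple[float, int, str] | None = None  # (fraction, shared, gene)
        for locus in by_chrom.get((cand.model.chrom, cand.model.strand), []):
            if not locus.span.overlaps(cand.model.location):
                continue
            shared, frac = _candidate_gene_overlap(cand, locus)
            if frac >= overlap_threshold:
                key = (frac, shared, locus.gene_id)
                if best is None or (
                    key[0] > best[0]
                    or (key[0] == best[0] and key[1] > best[1])
                    or (key[0] == best[0] and key[1] == best[1]
                        and key[2] < best[2])
                ):
                    best = key
        if best is not None:
            assignment[cand.candidate_id] = best[2]
        else:
            unassigned.append(cand)

    # cluster the leftovers into novel loci by the same >= threshold rule
    clusters, membership = collapse_redundant(
        [
            FLNCIsoformCandidate(c.candidate_id, c.model, c.flnc_read_count,
                                 c.percent_identity)
            for c in unassigned
        ],
        overlap_threshold,
    )
    groups: dict[str, list[FLNCIsoformCandidate]] = {}
    for cand in unassigned:
        groups.setdefault(membership[cand.candidate_id], []).append(cand)

    # number novel loci by leftmost start per chromosome
    cluster_list = []
    for rep_id, members in groups.items():
        chrom = members[0].model.chrom
        leftmost = min(c.model.location.start for c in members)
        cluster_list.append((chrom, leftmost, rep_id, members))
    cluster_list.sort(key=lambda x: (x[0], x[1], x[2]))

    novel_loci: list[GeneLocus] = []
    counter: dict[str, int] = {}
    for chrom, _, _, members in cluster_list:
        counter[chrom] = counter.get(chrom, 0) + 1
        gene_id = f"NG.{chrom}.{counter[chrom]}"
        transcripts = [
            TranscriptModel(
                transcript_id=c.candidate_id,
                exons=list(c.model.exons),
                gene_id=gene_id,
                source="isoseq",
            )
            for c in sorted(members, key=lambda c: c.candidate_id)
        ]
        novel_loci.append(GeneLocus(gene_id, transcripts, status="novel"))
        for c in members:
            assignment[c.candidate_id] = gene_id
    return assignment, novel_loci


# ---------------------------------------------------------------------------
# 4. isoform status


def classify_isoform_status(
    model: TranscriptModel,
    locus: GeneLocus,
    end_tolerance: int = 50,
) -> IsoformStatus:
    """Known vs novel classification of a model assigned to a locus.

    Known requires an annotated transcript of the locus with an identical
    intron chain whose 3' terminus lies within ``end_tolerance`` bases.
    Otherwise the reason is the first that applies of: new_intron (an
    intron no annotated transcript of the locus has), new_exon (exonic
    sequence more than ``end_tolerance`` bases outside the union of the
    locus's annotated exons), changed_3prime_end (chain matches but the 3'
    terminus moved), novel_locus (the model itself seeded a locus that has
    no previously annotated transcripts).

    Annotated means any transcript already carried by the locus, whatever
    its provenance — this makes the update pipeline idempotent: feeding an
    updated annotation's own transcripts back re-identifies every one of
    them as known.
    """
    member_ids = {t.transcript_id for t in locus.transcripts}
    if locus.status == "novel" and model.transcript_id in member_ids:
        return IsoformStatus(model.transcript_id, "novel", "novel_locus")
    refs = [t for t in locus.transcripts
            if t.transcript_id != model.transcript_id]
    if not refs:
        return IsoformStatus(model.transcript_id, "novel", "novel_locus")

    chain = model.intron_chain()
    for ref in refs:
        if chain == ref.intron_chain() and abs(
            model.three_prime_end() - ref.three_prime_end()
        ) <= end_tolerance:
            return IsoformStatus(model.transcript_id, "known", "matches_reference")

    ref_introns = {intron for r in refs for intron in r.intron_chain()}
    if any(intron not in ref_introns for intron in chain):
        return IsoformStatus(model.transcript_id, "novel", "new_intron")

    # new exonic sequence is counted inside the reference exon envelope only:
    # terminal extensions beyond the outermost reference exons are end
    # differences, not new exons
    ref_exon_union = _merge_intervals([e for r in refs for e in r.exons])
    lo, hi = ref_exon_union[0][0], ref_exon_union[-1][1]
    clipped = [
        (max(e.start, lo), min(e.end, hi))
        for e in model.exons
        if max(e.start, lo) < min(e.end, hi)
    ]
    inside_len = sum(e - s for s, e in clipped)
    outside = inside_len - _union_intersection_size(clipped, ref_exon_union)
    if outside > end_tolerance:
        return IsoformStatus(model.transcript_id, "novel", "new_exon")

    return IsoformStatus(model.transcript_id, "novel", "changed_3prime_end")


# ---------------------------------------------------------------------------
# 5. merge


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def merge_annotation(
    reference: GenomeAnnotation,
    representatives: list[FLNCIsoformCandidate],
    assignment: dict[str, str],
    novel_loci: list[GeneLocus],
    statuses: dict[str, IsoformStatus],
) -> GenomeAnnotation:
    """Merge classified representatives into the reference annotation.

    Known isoforms are dropped (they duplicate reference records). Novel
    isoforms in known loci are appended with ids ``<chrom>.<locus#>.<iso#>``
    (chromosome index . 1-based locus rank on the chromosome . transcript
    serial within the locus), the id shape conventional for Iso-seq-derived
    transcripts. Novel loci are appended whole.
    """
    updated = GenomeAnnotation(chromosomes=dict(reference.chromosomes))
    # locus rank per chromosome, by genomic start, for id construction
    rank: dict[str, int] = {}
    per_chrom: dict[str, list[GeneLocus]] = {}
    for locus in reference.loci.values():
        per_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom, loci in per_chrom.items():
        for i, locus in enumerate(
            sorted(loci, key=lambda L: (L.span.start, L.gene_id)), start=1
        ):
            rank[locus.gene_id] = i

    existing_ids = reference.transcript_ids()
    new_by_gene: dict[str, list[FLNCIsoformCandidate]] = {}
    for cand in representatives:
        status = statuses[cand.candidate_id]
        if status.status == "novel" and status.reason != "novel_locus":
            new_by_gene.setdefault(assignment[cand.candidate_id], []).append(cand)

    for gene_id, locus in reference.loci.items():
        transcripts = [
            TranscriptModel(
                t.transcript_id, list(t.exons), gene_id,
                list(t.utr5), list(t.utr3), t.source,
            )
            for t in locus.transcripts
        ]
        serial = len(transcripts)
        for cand in sorted(
            new_by_gene.get(gene_id, []),
            key=lambda c: (c.model.location.start, c.candidate_id),
        ):
            serial += 1
            tid = f"{_strip_chr(locus.chrom)}.{rank[gene_id]}.{serial}"
            while tid in existing_ids:
                logger.warning("transcript id collision for %s; suffixing", tid)
                tid += ".n"
            existing_ids.add(tid)
            transcripts.append(
                TranscriptModel(tid, list(cand.model.exons), gene_id,
                                source="isoseq")
            )
        updated.add_locus(GeneLocus(gene_id, transcripts, status=locus.status))

    for locus in sorted(novel_loci, key=lambda L: (L.chrom, L.span.start)):
        updated.add_locus(locus)
    return updated


# ---------------------------------------------------------------------------
# convenience pipeline


@dataclass
class AnnotationUpdate:
    """Bundle of all intermediate results of the annotation-update pipeline."""

    decisions: list[RetentionDecision]
    representatives: list[FLNCIsoformCandidate]
    membership: dict[str, str]
    assignment: dict[str, str]
    novel_loci: list[GeneLocus]
    statuses: dict[str, IsoformStatus]
    updated: GenomeAnnotation
    n_novel_isoforms: int = field(init=False)
    n_novel_loci: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_novel_isoforms = sum(
            1 for s in self.statuses.values() if s.status == "novel"
        )
        self.n_novel_loci = len(self.novel_loci)

    def decisions_frame(self) -> pd.DataFrame:
        rows = []
        status_by_id = self.statuses
        for d in self.decisions:
            rep = self.membership.get(d.candidate_id)
            st = status_by_id.get(rep) if rep else None
            rows.append(
                {
                    "candidate_id": d.candidate_id,
                    "kept": d.kept,
                    "criteria": ",".join(sorted(d.criteria_met)),
                    "representative": rep if d.kept else None,
                    "assigned_gene": self.assignment.get(rep) if rep else None,
                    "status": st.status if st else None,
                    "reason": st.reason if st else None,
                }
            )
        return pd.DataFrame(rows)


def update_annotation(
    candidates: list[FLNCIsoformCandidate],
    junctions: JunctionSet,
    reference: GenomeAnnotation,
    pid_threshold: float = 99.0,
    overlap_threshold: float = 0.20,
    end_tolerance: int = 50,
) -> AnnotationUpdate:
    """Run retain -> collapse -> assign -> classify -> merge in one call."""
    decisions = retain_candidates(candidates, junctions, reference, pid_threshold)
    kept_ids = {d.candidate_id for d in decisions if d.kept}
    kept = [c for c in candidates if c.candidate_id in kept_ids]
    representatives, membership = collapse_redundant(kept, overlap_threshold)
    assignment, novel_loci = assign_loci(
        representatives, reference, overlap_threshold
    )
    novel_gene_ids = {L.gene_id for L in novel_loci}
    statuses: dict[str, IsoformStatus] = {}
    for cand in representatives:
        gene_id = assignment[cand.candidate_id]
        if gene_id in novel_gene_ids:
            locus = next(L for L in novel_loci if L.gene_id == gene_id)
        else:
            locus = reference.loci[gene_id]
        status = classify_isoform_status(cand.model, locus, end_tolerance)
        statuses[cand.candidate_id] = IsoformStatus(
            cand.candidate_id, status.status, status.reason
        )
    updated = merge_annotation(
        reference, representatives, assignment, novel_loci, statuses
    )
    return AnnotationUpdate(
        decisions=decisions,
        representatives=representatives,
        membership=membership,
        assignment=assignment,
        novel_loci=novel_loci,
        statuses=statuses,
        updated=updated,
    )
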