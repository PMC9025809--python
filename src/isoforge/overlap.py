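"""Peak-to-feature annotation and gene-set overlap significance.

ChIP-seq peaks (or reads) are classified by their midpoint into one of six
genomic categories with a fixed priority — promoter, 5' UTR, 3' UTR, exon,
intron, intergenic — where the promoter is a configurable window around
each gene's transcription start site oriented by the gene's strand. Gene
sets derived from peaks and from differential isoforms are compared with
an exact hypergeometric upper-tail test (Fisher's one-sided test on the
2x2 table) against a configurable gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneLocus, GenomeAnnotation, GenomicInterval

__all__ = [
    "Peak",
    "FeatureAnnotation",
    "OverlapTestResult",
    "FeatureIndex",
    "annotate_feature",
    "feature_distribution",
    "peaks_to_genes",
    "gene_overlap_test",
    "CATEGORIES",
]

CATEGORIES = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "intergenic",
)


@dataclass
class Peak:
    """A strand-less enriched interval, optionally with per-sample counts."""

    peak_id: str
    location: GenomicInterval
    counts: dict[str, int] | None = None

    def midpoint(self) -> int:
        return (self.location.start + self.location.end) // 2


@dataclass(frozen=True)
class FeatureAnnotation:
    subject_id: str
    category: str
    assigned_gene: str | None

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (self.assigned_gene is None):
            raise ValueError(
                "assigned_gene must be None exactly for intergenic subjects"
            )


@dataclass(frozen=True)
class OverlapTestResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    odds_ratio: float


def _tss(locus: GeneLocus) -> int:
    return locus.span.start if locus.strand == "+" else locus.span.end


def _promoter_window(
    locus: GeneLocus, upstream: int, downstream: int
) -> tuple[int, int]:
    tss = _tss(locus)
    if locus.strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream, tss + upstream


class FeatureIndex:
    """Interval-tree index of an annotation for midpoint classification."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        promoter_upstream: int = 3000,
        promoter_downstream: int = 3000,
    ):
        self.annotation = annotation
        self.promoter_upstream = promoter_upstream
        self.promoter_downstream = promoter_downstream
        self._promoter: dict[str, IntervalTree] = {}
        self._gene: dict[str, IntervalTree] = {}
        self._utr5: dict[str, IntervalTree] = {}
        self._utr3: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        for locus in annotation.loci.values():
            chrom = locus.chrom
            ws, we = _promoter_window(locus, promoter_upstream, promoter_downstream)
            if ws < we:
                self._tree(self._promoter, chrom).addi(ws, we, locus)
            span = locus.span
            self._tree(self._gene, chrom).addi(span.start, span.end, locus)
            for t in locus.transcripts:
                for u in t.utr5:
                    self._tree(self._utr5, chrom).addi(u.start, u.end, locus)
                for u in t.utr3:
                    self._tree(self._utr3, chrom).addi(u.start, u.end, locus)
                for e in t.exons:
                    self._tree(self._exon, chrom).addi(e.start, e.end, locus)

    @staticmethod
    def _tree(store: dict[str, IntervalTree], chrom: str) -> IntervalTree:
        if chrom not in store:
            store[chrom] = IntervalTree()
        return store[chrom]

    def _hits(self, store: dict[str, IntervalTree], chrom: str, pos: int):
        tree = store.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def classify_point(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """(category, gene_id) for a genomic point, by category priority."""
        for category, store in (
            ("promoter", self._promoter),
            ("five_prime_utr", self._utr5),
            ("three_prime_utr", self._utr3),
            ("exon", self._exon),
            ("intron", self._gene),
        ):
            loci = self._hits(store, chrom, pos)
            if category == "exon":
                # exonic but outside UTRs: UTR hits already returned above
                pass
            if loci:
                gene = min(
                    loci,
                    key=lambda L: (abs(_tss(L) - pos), L.gene_id),
                ).gene_id
                return category, gene
        return "intergenic", None


def annotate_feature(
    subject: GenomicInterval,
    annotation: GenomeAnnotation | FeatureIndex,
    promoter_upstream: int = 3000,
    promoter_downstream: int = 3000,
    subject_id: str = "subject",
) -> FeatureAnnotation:
    """Classify a subject interval by its midpoint into one of six categories.

    Priority: promoter > 5' UTR > 3' UTR > exon > intron > intergenic; the
    assigned gene owns the winning feature (ties broken by TSS distance,
    then gene_id). UTR categories require UTR records in the annotation;
    exon means exonic outside any UTR; intron means inside a gene span but
    not exonic.
    """
    index = (
        annotation
        if isinstance(annotation, FeatureIndex)
        else FeatureIndex(annotation, promoter_upstream, promoter_downstream)
    )
    mid = (subject.start + subject.end) // 2
    category, gene = index.classify_point(subject.chrom, mid)
    return FeatureAnnotation(subject_id, category, gene)


def feature_distribution(
    subjects: list[GenomicInterval],
    annotation: GenomeAnnotation | FeatureIndex,
    promoter_upstream: int = 3000,
    promoter_downstream: int = 3000,
) -> tuple[dict[str, int], dict[str, float]]:
    """Category counts and proportions over a set of subject intervals.

    Every subject lands in exactly one category, so the counts sum to the
    number of subjects and the proportions to 1 (for non-empty input).
    """
    index = (
        annotation
        if isinstance(annotation, FeatureIndex)
        else FeatureIndex(annotation, promoter_upstream, promoter_downstream)
    )
    counts = {c: 0 for c in CATEGORIES}
    for i, s in enumerate(subjects):
        ann = annotate_feature(s, index, subject_id=f"s{i}")
        counts[ann.category] += 1
    total = len(subjects)
    proportions = {
        c: (counts[c] / total if total else 0.0) for c in CATEGORIES
    }
    return counts, proportions


def peaks_to_genes(
    peaks: list[Peak],
    annotation: GenomeAnnotation,
    promoter_upstream: int = 3000,
    promoter_downstream: int = 3000,
) -> set[str]:
    """Genes whose body or promoter window overlaps any peak by >= 1 base."""
    trees: dict[str, IntervalTree] = {}
    for locus in annotation.loci.values():
        span = locus.span
        ws, we = _promoter_window(locus, promoter_upstream, promoter_downstream)
        lo, hi = min(span.start, ws), max(span.end, we)
        trees.setdefault(locus.chrom, IntervalTree()).addi(lo, hi, locus.gene_id)
    genes: set[str] = set()
    for peak in peaks:
        tree = trees.get(peak.location.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(peak.location.start, peak.location.end):
            genes.add(iv.data)
    return genes


def gene_overlap_test(
    set_a: set[str], set_b: set[str], universe: int
) -> OverlapTestResult:
    """Exact hypergeometric upper-tail test of two gene sets' overlap.

    p = P(X >= |A ∩ B|) with X ~ Hypergeom(universe, |A|, |B|); the odds
    ratio comes from the 2x2 table (overlap, A-only, B-only, neither),
    with the conventions +inf / 0 / 1 for degenerate tables.
    """
    if universe < 1:
        raise ValueError("universe must be >= 1")
    n_a, n_b = len(set_a), len(set_b)
    n_union = len(set_a | set_b)
    if universe < n_union:
        raise ValueError(
            f"universe ({universe}) smaller than |A ∪ B| ({n_union})"
        )
    overlap = len(set_a & set_b)
    p = float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))
    p = min(max(p, 0.0), 1.0)
    a = overlap
    b = n_a - overlap
    c = n_b - overlap
    d = universe - n_a - n_b + overlap
    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        odds = 1.0
    elif bc == 0:
        odds = float("inf")
    elif ad == 0:
        odds = 0.0
    else:
        odds = ad / bc
    return OverlapTestResult(
        overlap=overlap,
        size_a=n_a,
        size_b=n_b,
        universe=universe,
        p_value=p,
        odds_ratio=odds,
    )
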