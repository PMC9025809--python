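"""Synthetic study generator: every pipeline input plus ground truth.

Emulates the study design the analysis modules assume: a multi-gene,
multi-isoform reference annotation with UTRs; full-length long-read
isoform candidates that are either copies of reference transcripts or
carry exactly one planted perturbation (an alternative-splicing event or
a 3' end shift) with read-count and identity distributions; a short-read
junction set with incomplete support; negative-binomial count matrices
for a two-group (3 vs 3) design with a planted differentially expressed
fraction; and ChIP-style peak sets placed across genomic feature
categories with a planted differential fraction. Every emitted object has
a truth row, so each analysis stage can be scored without external data.

All generators are pure functions of (config, seed): the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import FLNCIsoformCandidate, JunctionSet
from .core import (
    GeneLocus,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    write_bed12,
    write_gff,
)
from .differential import CountMatrix
from .overlap import CATEGORIES, Peak, _promoter_window

__all__ = [
    "SimulationConfig",
    "simulate_reference_annotation",
    "simulate_flnc_candidates",
    "simulate_junctions",
    "simulate_counts",
    "simulate_peaksets",
    "simulate_event_pairs",
    "simulate_workspace",
]

AS_PERTURBATIONS = (
    "exon_skipping",
    "intron_retention",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive",
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the design
    the analysis assumes (two groups of three samples, NB dispersion 0.1,
    a 10% differential fraction at |log2FC| = 2)."""

    seed: int = 0
    # reference annotation
    n_genes: int = 60
    n_chromosomes: int = 3
    mean_exons: float = 6.0
    utr_probability: float = 0.6
    extra_transcript_probability: float = 0.5
    chromosome_length: int | None = None
    # FLNC candidates
    n_candidates: int = 150
    novel_fraction: float = 0.5
    three_prime_shift_fraction: float = 0.15
    event_mix: dict = field(
        default_factory=lambda: {
            "exon_skipping": 0.35,
            "intron_retention": 0.25,
            "alt_5ss": 0.15,
            "alt_3ss": 0.15,
            "mutually_exclusive": 0.10,
        }
    )
    mean_extra_reads: float = 2.0
    pid_mean: float = 99.0
    pid_sd: float = 0.8
    end_tolerance: int = 50
    junction_support_probability: float = 0.9
    # count matrices
    n_samples_per_group: int = 3
    de_fraction: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    # peaks
    n_peaks: int = 200
    differential_peak_fraction: float = 0.2
    peak_log2fc: float = 2.0
    n_peak_replicates: int = 2
    peak_dispersion: float = 0.05
    promoter_upstream: int = 3000
    promoter_downstream: int = 3000
    feature_placement_mix: dict = field(
        default_factory=lambda: {
            "intergenic": 0.50,
            "intron": 0.24,
            "promoter": 0.12,
            "exon": 0.08,
            "five_prime_utr": 0.02,
            "three_prime_utr": 0.04,
        }
    )

    def __post_init__(self) -> None:
        for name, mix in (("event_mix", self.event_mix),
                          ("feature_placement_mix", self.feature_placement_mix)):
            if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1) > 1e-9:
                raise ValueError(f"{name} proportions must be >= 0 and sum to 1")
        for p in (self.utr_probability, self.novel_fraction,
                  self.junction_support_probability, self.de_fraction,
                  self.differential_peak_fraction,
                  self.three_prime_shift_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """A deterministic per-stage generator (stage id keeps stages
        independent of call order)."""
        return np.random.default_rng([self.seed % (2**31), stream])


# ---------------------------------------------------------------------------
# reference annotation


def _chrom_names(n: int) -> list[str]:
    # non-numeric final name exercises lexicographic chromosome handling
    return [f"chr{i}" for i in range(1, n)] + ["chrX"]


def _draw_exon_chain(
    rng: np.random.Generator, start: int, chrom: str, strand: str,
    mean_exons: float,
) -> list[GenomicInterval]:
    n_exons = max(1, int(rng.poisson(mean_exons - 1)) + 1)
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(80, 300))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        if i < n_exons - 1:
            pos += length + int(rng.integers(200, 2000))
    return exons


def simulate_reference_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """A multi-chromosome reference with 1-3 transcripts per locus.

    Loci are packed left to right with intergenic gaps, never overlapping
    within a strand; secondary transcripts are splice variants of the
    primary (generated with the same perturbation machinery the candidate
    simulator uses), so reference loci themselves carry AS diversity.
    """
    rng = config.rng(1)
    chroms = _chrom_names(config.n_chromosomes)
    per_chrom = np.array_split(np.arange(config.n_genes), len(chroms))
    loci: list[GeneLocus] = []
    chrom_lengths: dict[str, int] = {}
    gene_counter = 0
    for chrom, idxs in zip(chroms, per_chrom):
        cursor = 8000
        for _ in idxs:
            gene_counter += 1
            gene_id = f"G{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _draw_exon_chain(
                rng, cursor, chrom, strand, config.mean_exons
            )
            primary = TranscriptModel(
                f"{gene_id}.t1", exons, gene_id, source="reference"
            )
            transcripts = [primary]
            n_extra = int(rng.random() < config.extra_transcript_probability) \
                + int(rng.random() < config.extra_transcript_probability / 2)
            serial = 1
            for _ in range(n_extra):
                etype = rng.choice(AS_PERTURBATIONS)
                new_exons = _perturb_exons(primary.exons, str(etype), rng)
                if new_exons is None:
                    continue
                serial += 1
                transcripts.append(
                    TranscriptModel(
                        f"{gene_id}.t{serial}", new_exons, gene_id,
                        source="reference",
                    )
                )
            if rng.random() < config.utr_probability:
                _attach_utrs(transcripts, rng)
            locus = GeneLocus(gene_id, transcripts, status="known")
            loci.append(locus)
            cursor = locus.span.end + int(rng.integers(12000, 30000))
        chrom_lengths[chrom] = cursor + 8000
        if config.chromosome_length is not None:
            if cursor > config.chromosome_length:
                raise ValueError(
                    f"cannot pack {len(idxs)} loci into a "
                    f"{config.chromosome_length}-base chromosome {chrom}"
                )
            chrom_lengths[chrom] = config.chromosome_length
    ann = GenomeAnnotation(loci)
    for chrom, length in chrom_lengths.items():
        ann.chromosomes[chrom] = length
    return ann


def _attach_utrs(transcripts: list[TranscriptModel],
                 rng: np.random.Generator) -> None:
    """Annotate terminal portions of each transcript's end exons as UTRs."""
    for t in transcripts:
        first, last = t.exons[0], t.exons[-1]
        l5 = int(rng.integers(20, max(21, len(first) // 2)))
        l3 = int(rng.integers(20, max(21, len(last) // 2)))
        if t.strand == "+":
            t.utr5 = [GenomicInterval(t.chrom, first.start, first.start + l5,
                                      t.strand)]
            t.utr3 = [GenomicInterval(t.chrom, last.end - l3, last.end,
                                      t.strand)]
        else:
            t.utr5 = [GenomicInterval(t.chrom, last.end - l5, last.end,
                                      t.strand)]
            t.utr3 = [GenomicInterval(t.chrom, first.start, first.start + l3,
                                      t.strand)]


# ---------------------------------------------------------------------------
# planted perturbations


def _perturb_exons(
    exons: list[GenomicInterval], etype: str, rng: np.random.Generator
) -> list[GenomicInterval] | None:
    """Apply one AS perturbation to an exon chain; None when infeasible."""
    chrom, strand = exons[0].chrom, exons[0].strand
    n = len(exons)

    def gi(s: int, e: int) -> GenomicInterval:
        return GenomicInterval(chrom, s, e, strand)

    if etype == "exon_skipping":
        if n < 3:
            return None
        i = int(rng.integers(1, n - 1))
        return exons[:i] + exons[i + 1:]

    if etype == "intron_retention":
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        merged = gi(exons[i].start, exons[i + 1].end)
        return exons[:i] + [merged] + exons[i + 2:]

    if etype in ("alt_5ss", "alt_3ss"):
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        gap = exons[i + 1].start - exons[i].end
        if gap < 40:
            return None
        delta = int(rng.integers(10, min(60, gap - 20) + 1))
        # left intron boundary is the donor on '+', the acceptor on '-'
        move_left = (etype == "alt_5ss") == (strand == "+")
        out = list(exons)
        if move_left:
            out[i] = gi(exons[i].start, exons[i].end + delta)
        else:
            out[i + 1] = gi(exons[i + 1].start - delta, exons[i + 1].end)
        return out

    if etype == "mutually_exclusive":
        if n < 3:
            return None
        i = int(rng.integers(1, n - 1))
        gap = exons[i + 1].start - exons[i].end
        new_len = int(rng.integers(60, 121))
        if gap < new_len + 40:
            return None
        offset = int(rng.integers(20, gap - new_len - 20 + 1))
        new_exon = gi(exons[i].end + offset, exons[i].end + offset + new_len)
        return exons[:i] + [new_exon] + exons[i + 1:]

    raise ValueError(f"unknown perturbation {etype!r}")


def _shift_3prime(
    exons: list[GenomicInterval], delta: int
) -> list[GenomicInterval]:
    """Extend the transcript's 3' terminal exon outward by delta bases."""
    chrom, strand = exons[0].chrom, exons[0].strand
    out = list(exons)
    if strand == "+":
        last = exons[-1]
        out[-1] = GenomicInterval(chrom, last.start, last.end + delta, strand)
    else:
        first = exons[0]
        out[0] = GenomicInterval(
            chrom, max(0, first.start - delta), first.end, strand
        )
    return out


def _truth_status(
    exons: list[GenomicInterval], locus: GeneLocus, end_tolerance: int
) -> tuple[str, str]:
    """Ground-truth known/novel status of an exon chain within its locus,
    computed by direct set arithmetic over the locus's reference models."""
    model = TranscriptModel("_truth", list(exons), locus.gene_id)
    chain = model.intron_chain()
    refs = locus.reference_transcripts()
    for ref in refs:
        if chain == ref.intron_chain() and abs(
            model.three_prime_end() - ref.three_prime_end()
        ) <= end_tolerance:
            return "known", "matches_reference"
    ref_introns = {j for r in refs for j in r.intron_chain()}
    if any(j not in ref_introns for j in chain):
        return "novel", "new_intron"
    covered = _merge([(e.start, e.end) for r in refs for e in r.exons])
    lo, hi = covered[0][0], covered[-1][1]
    # terminal extensions past the reference exon envelope are end
    # differences, not new exonic sequence
    outside = 0
    for e in exons:
        es, ee = max(e.start, lo), min(e.end, hi)
        if es >= ee:
            continue
        pos = es
        for s, t in covered:
            if t <= pos or s >= ee:
                continue
            if s > pos:
                outside += s - pos
            pos = min(t, ee)
        outside += max(0, ee - pos)
    if outside > end_tolerance:
        return "novel", "new_exon"
    return "novel", "changed_3prime_end"


# ---------------------------------------------------------------------------
# FLNC candidates


def simulate_flnc_candidates(
    reference: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[FLNCIsoformCandidate], pd.DataFrame]:
    """Candidates = reference copies (small 3' jitter) + perturbed novels.

    Each novel candidate carries exactly one planted perturbation: an AS
    event drawn from the configured mix or a 3' end shift beyond the end
    tolerance. Read counts are 1 + Poisson(mean_extra_reads); identities
    are normal(pid_mean, pid_sd) clipped to [90, 100]. Truth rows record
    the planted perturbation, the expected known/novel status and reason,
    and the support-independent retention criteria C1/C2/C4 (C3 is filled
    in by ``simulate_junctions``, which draws junction support).
    """
    rng = config.rng(2)
    loci = sorted(reference.loci.values(), key=lambda L: L.gene_id)
    universe = reference.intron_universe()
    types = sorted(config.event_mix)
    probs = np.array([config.event_mix[t] for t in types])
    candidates: list[FLNCIsoformCandidate] = []
    rows = []
    for i in range(config.n_candidates):
        locus = loci[int(rng.integers(0, len(loci)))]
        source = locus.transcripts[int(rng.integers(0, len(locus.transcripts)))]
        planted = "none"
        if rng.random() < config.novel_fraction:
            if rng.random() < config.three_prime_shift_fraction:
                planted = "three_prime_shift"
                delta = int(rng.integers(config.end_tolerance + 50,
                                         config.end_tolerance + 250))
                exons = _shift_3prime(source.exons, delta)
            else:
                exons = None
                for _ in range(20):  # redraw if the chain cannot host the type
                    planted = str(rng.choice(types, p=probs))
                    exons = _perturb_exons(source.exons, planted, rng)
                    if exons is not None:
                        break
                if exons is None:
                    planted = "none"
                    exons = list(source.exons)
        else:
            jitter = int(rng.integers(0, min(21, config.end_tolerance)))
            exons = _shift_3prime(source.exons, jitter) if jitter else \
                list(source.exons)
        count = 1 + int(rng.poisson(config.mean_extra_reads))
        pid = float(np.clip(rng.normal(config.pid_mean, config.pid_sd),
                            90.0, 100.0))
        cid = f"FLNC{i + 1:05d}"
        model = TranscriptModel(cid, exons, source="isoseq")
        candidates.append(FLNCIsoformCandidate(cid, model, count, pid))
        status, reason = _truth_status(exons, locus, config.end_tolerance)
        chain = model.intron_chain()
        rows.append(
            {
                "candidate_id": cid,
                "source_transcript": source.transcript_id,
                "source_gene": locus.gene_id,
                "planted": planted,
                "true_status": status,
                "true_reason": reason,
                "flnc_read_count": count,
                "percent_identity": pid,
                "c1_multiread": count >= 2,
                "c2_single_read_high_pid": count == 1 and pid > 99.0,
                "c4_events_annotated": all(
                    (model.chrom, model.strand, d, a) in universe
                    for d, a in chain
                ),
            }
        )
    return candidates, pd.DataFrame(rows)


def simulate_junctions(
    reference: GenomeAnnotation,
    candidates: list[FLNCIsoformCandidate],
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[JunctionSet, pd.DataFrame | None]:
    """Short-read junction evidence with incomplete support.

    Every true intron (reference or candidate) enters the set
    independently with ``junction_support_probability``. When the
    candidate truth table is supplied, its ``c3_junctions_supported`` and
    derived ``true_kept`` columns are filled in and the updated table
    returned.
    """
    rng = config.rng(3)
    all_introns: set[tuple[str, str, int, int]] = set(reference.intron_universe())
    for cand in candidates:
        m = cand.model
        for d, a in m.intron_chain():
            all_introns.add((m.chrom, m.strand, d, a))
    included = {
        j for j in sorted(all_introns)
        if rng.random() < config.junction_support_probability
    }
    junctions = JunctionSet(included)
    if truth is None:
        return junctions, None
    truth = truth.copy()
    supported = []
    for cand in candidates:
        m = cand.model
        supported.append(
            all((m.chrom, m.strand, d, a) in included
                for d, a in m.intron_chain())
        )
    truth["c3_junctions_supported"] = supported
    truth["true_kept"] = (
        truth["c1_multiread"]
        | truth["c2_single_read_high_pid"]
        | truth["c3_junctions_supported"]
        | truth["c4_events_annotated"]
    )
    return junctions, truth


def simulate_event_pairs(
    config: SimulationConfig, n_pairs: int = 500
) -> list[tuple[TranscriptModel, TranscriptModel, str]]:
    """(original, perturbed, planted type) pairs for classifier scoring.

    Each pair differs by exactly one planted AS event drawn from the
    configured mix, placed on a freshly drawn multi-exon chain.
    """
    rng = config.rng(4)
    types = sorted(config.event_mix)
    probs = np.array([config.event_mix[t] for t in types])
    pairs = []
    k = 0
    while len(pairs) < n_pairs:
        k += 1
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{int(rng.integers(1, 4))}"
        exons = _draw_exon_chain(rng, 10000, chrom, strand,
                                 max(4.0, config.mean_exons))
        if len(exons) < 3:
            continue
        etype = str(rng.choice(types, p=probs))
        perturbed = _perturb_exons(exons, etype, rng)
        if perturbed is None:
            continue
        a = TranscriptModel(f"pair{k}.ref", exons, f"gene{k}")
        b = TranscriptModel(f"pair{k}.alt", perturbed, f"gene{k}")
        pairs.append((a, b, etype))
    return pairs


# ---------------------------------------------------------------------------
# counts


def _nb_draws(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(
    feature_ids: list[str], config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-group NB count matrix with a planted DE fraction.

    Baselines are log-normal(baseline_log_mean, baseline_log_sd); a
    ``de_fraction`` of features receives ±planted_log2fc (random sign) in
    group 2; per-sample library-depth factors in [0.75, 1.3] make the
    size-factor stage non-trivial.
    """
    rng = config.rng(5)
    n_feat = len(feature_ids)
    if n_feat < 1:
        raise ValueError("need at least one feature")
    n = config.n_samples_per_group
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                             n_feat))
    is_de = rng.random(n_feat) < config.de_fraction
    sign = np.where(rng.random(n_feat) < 0.5, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * config.planted_log2fc, 0.0)
    depth = rng.uniform(0.75, 1.3, 2 * n)
    mean1 = base[:, None] * depth[None, :n]
    mean2 = (base * 2.0**true_lfc)[:, None] * depth[None, n:]
    counts = np.concatenate(
        [
            _nb_draws(rng, mean1, config.nb_dispersion),
            _nb_draws(rng, mean2, config.nb_dispersion),
        ],
        axis=1,
    )
    samples = [f"g1_s{i + 1}" for i in range(n)] + [
        f"g2_s{i + 1}" for i in range(n)
    ]
    matrix = CountMatrix(
        feature_ids=list(feature_ids),
        sample_ids=samples,
        counts=counts,
        group_labels=["group1"] * n + ["group2"] * n,
    )
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "is_de": is_de,
            "true_log2fc": true_lfc,
            "baseline_mean": base,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# peaks


def _subtract(
    regions: list[tuple[int, int]], cut: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for s, e in regions:
        pieces = [(s, e)]
        for cs, ce in cut:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or pe <= cs:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(p for p in out if p[1] > p[0])


def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not pairs:
        return []
    pairs = sorted(pairs)
    out = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _category_regions(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Per-chromosome interval sets for each feature category, built by
    region algebra with the same priority the point classifier applies."""
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, length in annotation.chromosomes.items():
        promoter, utr5, utr3, exon, span = [], [], [], [], []
        for locus in annotation.loci.values():
            if locus.chrom != chrom:
                continue
            ws, we = _promoter_window(
                locus, config.promoter_upstream, config.promoter_downstream
            )
            promoter.append((max(0, ws), min(length, we)))
            span.append((locus.span.start, locus.span.end))
            for t in locus.transcripts:
                utr5.extend((u.start, u.end) for u in t.utr5)
                utr3.extend((u.start, u.end) for u in t.utr3)
                exon.extend((e.start, e.end) for e in t.exons)
        promoter, utr5, utr3, exon, span = map(
            _merge, (promoter, utr5, utr3, exon, span)
        )
        margin = [(500, length - 500)] if length > 1000 else []
        regions = {
            "promoter": promoter,
            "five_prime_utr": _subtract(utr5, promoter),
            "three_prime_utr": _subtract(_subtract(utr3, promoter), utr5),
            "exon": _subtract(_subtract(_subtract(exon, promoter), utr5), utr3),
            "intron": _subtract(_subtract(span, promoter), exon),
            "intergenic": _subtract(_subtract(margin, promoter), span),
        }
        out[chrom] = {
            cat: _subtract(iv, [(0, 500), (length - 500, length)])
            if length > 1000 else iv
            for cat, iv in regions.items()
        }
    return out


def _sample_position(
    rng: np.random.Generator,
    regions: dict[str, dict[str, list[tuple[int, int]]]],
    category: str,
) -> tuple[str, int] | None:
    choices = [
        (chrom, iv)
        for chrom, cats in sorted(regions.items())
        for iv in cats[category]
    ]
    total = sum(e - s for _, (s, e) in choices)
    if total == 0:
        return None
    u = int(rng.integers(0, total))
    for chrom, (s, e) in choices:
        if u < e - s:
            return chrom, s + u
        u -= e - s
    raise AssertionError("unreachable")


def simulate_peaksets(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[Peak], CountMatrix, pd.DataFrame]:
    """Peaks placed across feature categories with planted differentials.

    Peak midpoints are drawn from category regions derived by interval
    algebra (the ground truth for feature classification); counts are NB
    across two conditions with ``n_peak_replicates`` each, and a
    ``differential_peak_fraction`` of peaks carries ±peak_log2fc
    enrichment in condition 2.
    """
    rng = config.rng(6)
    regions = _category_regions(annotation, config)
    cats = sorted(config.feature_placement_mix)
    probs = np.array([config.feature_placement_mix[c] for c in cats])
    peaks: list[Peak] = []
    truth_rows = []
    while len(peaks) < config.n_peaks:
        category = str(rng.choice(cats, p=probs))
        hit = _sample_position(rng, regions, category)
        if hit is None:
            continue
        chrom, mid = hit
        half = int(rng.integers(60, 200))
        pid = f"peak{len(peaks) + 1:04d}"
        peaks.append(
            Peak(pid, GenomicInterval(chrom, mid - half, mid + half, "+"))
        )
        truth_rows.append({"peak_id": pid, "true_category": category})
    truth = pd.DataFrame(truth_rows)

    n_rep = config.n_peak_replicates
    base = np.exp(rng.normal(np.log(50.0), 0.8, config.n_peaks))
    is_diff = rng.random(config.n_peaks) < config.differential_peak_fraction
    sign = np.where(rng.random(config.n_peaks) < 0.5, 1.0, -1.0)
    true_lfc = np.where(is_diff, sign * config.peak_log2fc, 0.0)
    depth = rng.uniform(0.8, 1.25, 2 * n_rep)
    mean1 = base[:, None] * depth[None, :n_rep]
    mean2 = (base * 2.0**true_lfc)[:, None] * depth[None, n_rep:]
    counts = np.concatenate(
        [
            _nb_draws(rng, mean1, config.peak_dispersion),
            _nb_draws(rng, mean2, config.peak_dispersion),
        ],
        axis=1,
    )
    samples = [f"tender_r{i + 1}" for i in range(n_rep)] + [
        f"tough_r{i + 1}" for i in range(n_rep)
    ]
    matrix = CountMatrix(
        feature_ids=[p.peak_id for p in peaks],
        sample_ids=samples,
        counts=counts,
        group_labels=["tender"] * n_rep + ["tough"] * n_rep,
    )
    for peak, row in zip(peaks, counts):
        peak.counts = dict(zip(samples, (int(x) for x in row)))
    truth["is_differential"] = is_diff
    truth["true_log2fc"] = true_lfc
    return peaks, matrix, truth


# ---------------------------------------------------------------------------
# whole workspace


def simulate_workspace(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> dict:
    """Generate every pipeline input plus truth tables in one call.

    Returns a dict of in-memory objects; when ``outdir`` is given, also
    writes the on-disk formats the pipeline consumes (reference GFF3,
    candidate BED12 + sidecar TSV, junction BED, count/group TSVs, peak
    BED + count TSV) and the truth TSVs.
    """
    reference = simulate_reference_annotation(config)
    candidates, cand_truth = simulate_flnc_candidates(reference, config)
    junctions, cand_truth = simulate_junctions(
        reference, candidates, config, cand_truth
    )
    isoform_ids = [t.transcript_id for t in reference.transcripts()]
    counts, count_truth = simulate_counts(isoform_ids, config)
    peaks, peak_counts, peak_truth = simulate_peaksets(reference, config)
    ws = {
        "config": config,
        "reference": reference,
        "candidates": candidates,
        "candidate_truth": cand_truth,
        "junctions": junctions,
        "isoform_counts": counts,
        "isoform_truth": count_truth,
        "peaks": peaks,
        "peak_counts": peak_counts,
        "peak_truth": peak_truth,
    }
    if outdir is not None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        write_gff(reference, os.path.join(outdir, "reference.gff3"))
        write_bed12([c.model for c in candidates],
                    os.path.join(outdir, "candidates.bed12"))
        pd.DataFrame(
            {
                "candidate_id": [c.candidate_id for c in candidates],
                "flnc_read_count": [c.flnc_read_count for c in candidates],
                "percent_identity": [c.percent_identity for c in candidates],
            }
        ).to_csv(os.path.join(outdir, "candidates.tsv"), sep="\t", index=False)
        junctions.write_bed(os.path.join(outdir, "junctions.bed"))
        counts.to_tsv(os.path.join(outdir, "isoform_counts.tsv"),
                      os.path.join(outdir, "isoform_groups.tsv"))
        with open(os.path.join(outdir, "peaks.bed"), "w") as fh:
            for p in peaks:
                fh.write(
                    f"{p.location.chrom}\t{p.location.start}\t"
                    f"{p.location.end}\t{p.peak_id}\t0\t+\n"
                )
        peak_counts.to_tsv(os.path.join(outdir, "peak_counts.tsv"),
                           os.path.join(outdir, "peak_groups.tsv"))
        cand_truth.to_csv(os.path.join(outdir, "truth_candidates.tsv"),
                          sep="\t", index=False)
        count_truth.to_csv(os.path.join(outdir, "truth_isoforms.tsv"),
                           sep="\t", index=False)
        peak_truth.to_csv(os.path.join(outdir, "truth_peaks.tsv"),
                          sep="\t", index=False)
    return ws
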