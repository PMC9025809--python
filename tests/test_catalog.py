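"""Retention criteria, redundancy collapse, locus assignment and merging."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from isoforge.catalog import (
    FLNCIsoformCandidate,
    JunctionSet,
    assign_loci,
    classify_isoform_status,
    collapse_redundant,
    merge_annotation,
    retain_candidates,
    update_annotation,
)
from isoforge.core import GeneLocus, GenomeAnnotation, exonic_overlap
from .conftest import make_transcript


def cand(cid, exons, reads=2, pid=95.0, chrom="chr1", strand="+"):
    return FLNCIsoformCandidate(
        cid,
        make_transcript(cid, exons, chrom=chrom, strand=strand, source="isoseq"),
        reads,
        pid,
    )


@pytest.fixture
def reference(three_exon_gene):
    return GenomeAnnotation([three_exon_gene])


class TestRetention:
    # exons [(100,200),(300,400)] carry intron (200,300), absent from the
    # reference gene (introns (200,300) IS in T1's chain!) -> use (150,250)
    def test_multiread_kept_despite_unsupported_introns(self, reference):
        c = cand("c1", [(50, 150), (250, 350)], reads=2, pid=90.0)
        (d,) = retain_candidates([c], JunctionSet(), reference)
        assert d.kept and d.criteria_met == {"C1_multiread"}

    def test_single_low_pid_unsupported_dropped(self, reference):
        c = cand("c1", [(50, 150), (250, 350)], reads=1, pid=98.5)
        (d,) = retain_candidates([c], JunctionSet(), reference)
        assert not d.kept and not d.criteria_met

    def test_single_read_high_pid_kept(self, reference):
        c = cand("c1", [(50, 150), (250, 350)], reads=1, pid=99.5)
        (d,) = retain_candidates([c], JunctionSet(), reference)
        assert d.kept and "C2_single_read_high_pid" in d.criteria_met

    def test_junction_support_keeps_single_read(self, reference):
        c = cand("c1", [(50, 150), (250, 350), (500, 600)], reads=1, pid=95.0)
        junctions = JunctionSet(
            {("chr1", "+", 150, 250), ("chr1", "+", 350, 500)}
        )
        (d,) = retain_candidates([c], junctions, reference)
        assert d.kept and "C3_junctions_supported" in d.criteria_met

    def test_reference_annotated_introns_keep_candidate(self, reference):
        # candidate's introns (200,300),(400,500) both in the reference chain
        c = cand("c1", [(120, 200), (300, 400), (500, 580)], reads=1, pid=95.0)
        (d,) = retain_candidates([c], JunctionSet(), reference)
        assert "C4_events_annotated" in d.criteria_met

    def test_mono_exonic_vacuously_junction_supported(self, reference):
        c = cand("c1", [(5000, 5200)], reads=1, pid=95.0)
        (d,) = retain_candidates([c], JunctionSet(), reference)
        assert d.kept
        assert {"C3_junctions_supported", "C4_events_annotated"} <= d.criteria_met

    def test_pid_threshold_validated(self, reference):
        with pytest.raises(ValueError):
            retain_candidates([], JunctionSet(), reference, pid_threshold=120)

    @given(
        reads=st.integers(1, 5),
        pid=st.floats(90, 100),
        extra_reads=st.integers(0, 3),
        extra_pid=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_keeping_is_monotone_in_support(
        self, reads, pid, extra_reads, extra_pid
    ):
        """Raising read count or identity never un-keeps a candidate."""
        gene = GeneLocus(
            "G1",
            [make_transcript("T1", [(100, 200), (300, 400), (500, 600)])],
        )
        reference = GenomeAnnotation([gene])
        base = cand("c", [(50, 150), (250, 350)], reads, min(pid, 100.0))
        more = cand(
            "c",
            [(50, 150), (250, 350)],
            reads + extra_reads,
            min(pid + extra_pid, 100.0),
        )
        (d1,) = retain_candidates([base], JunctionSet(), reference)
        (d2,) = retain_candidates([more], JunctionSet(), reference)
        assert d2.kept or not d1.kept


def brute_force_clusters(candidates, threshold=0.20):
    """Transitive closure over all pairwise >= threshold links."""
    links = {c.candidate_id: {c.candidate_id} for c in candidates}
    for a, b in itertools.combinations(candidates, 2):
        same = (
            a.model.chrom == b.model.chrom and a.model.strand == b.model.strand
        )
        if same and exonic_overlap(a.model, b.model).fraction_of_shorter >= threshold:
            merged = links[a.candidate_id] | links[b.candidate_id]
            for cid in merged:
                links[cid] = merged
    return {frozenset(v) for v in links.values()}


class TestCollapse:
    def test_identical_models_merge_and_sum_reads(self):
        a = cand("a", [(100, 200)], reads=2)
        b = cand("b", [(100, 200)], reads=3)
        reps, members = collapse_redundant([a, b])
        assert len(reps) == 1
        assert reps[0].flnc_read_count == 5
        assert members == {"a": "b", "b": "b"}  # higher read count wins

    def test_low_overlap_stays_distinct(self):
        # b shares 10 of its 100 exonic bases with a -> below 20%
        a = cand("a", [(0, 300)])
        b = cand("b", [(290, 390)])
        reps, _ = collapse_redundant([a, b])
        assert len(reps) == 2

    def test_single_linkage_chains(self):
        a = cand("a", [(0, 100)])
        b = cand("b", [(50, 150)])
        c = cand("c", [(120, 220)])
        reps, members = collapse_redundant([a, b, c])
        assert len(reps) == 1
        assert len(set(members.values())) == 1

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_linkage_closure_oracle(self, data):
        n = data.draw(st.integers(1, 6))
        cands = []
        for i in range(n):
            start = data.draw(st.integers(0, 300), label=f"s{i}")
            length = data.draw(st.integers(20, 200), label=f"l{i}")
            cands.append(cand(f"c{i}", [(start, start + length)]))
        reps, members = collapse_redundant(cands)
        oracle = brute_force_clusters(cands)
        got = {}
        for cid, rep in members.items():
            got.setdefault(rep, set()).add(cid)
        assert {frozenset(v) for v in got.values()} == oracle
        # read-count conservation
        assert sum(r.flnc_read_count for r in reps) == sum(
            c.flnc_read_count for c in cands
        )


class TestAssignLoci:
    def test_identical_model_joins_its_gene(self, reference):
        c = cand("c", [(100, 200), (300, 400), (500, 600)])
        assignment, novel = assign_loci([c], reference)
        assert assignment == {"c": "G1"} and not novel

    def test_nonoverlapping_candidate_seeds_novel_locus(self, reference):
        c = cand("c", [(20_000, 20_500)])
        assignment, novel = assign_loci([c], reference)
        assert assignment["c"] == "NG.chr1.1"
        assert novel[0].status == "novel"

    def test_argmax_over_candidate_gene_fractions(self):
        """All (candidate, gene) overlap fractions enumerated by hand:
        candidate [0,100) shares 30% with A, 25% with B -> A wins."""
        gene_a = GeneLocus("A", [make_transcript("tA", [(0, 30), (500, 700)])])
        gene_b = GeneLocus("B", [make_transcript("tB", [(75, 100), (900, 1100)])])
        ann = GenomeAnnotation([gene_a, gene_b])
        c = cand("c", [(0, 100)])
        frac_a = exonic_overlap(c.model, gene_a.transcripts[0]).fraction_of_shorter
        frac_b = exonic_overlap(c.model, gene_b.transcripts[0]).fraction_of_shorter
        assert frac_a == pytest.approx(0.30) and frac_b == pytest.approx(0.25)
        assignment, _ = assign_loci([c], ann)
        assert assignment["c"] == "A"

    def test_novel_locus_ids_numbered_by_position(self, reference):
        c2 = cand("right", [(40_000, 40_500)])
        c1 = cand("left", [(20_000, 20_500)])
        assignment, novel = assign_loci([c2, c1], reference)
        assert assignment["left"] == "NG.chr1.1"
        assert assignment["right"] == "NG.chr1.2"


class TestClassifyStatus:
    def test_exact_match_is_known(self, three_exon_gene):
        m = make_transcript("m", [(100, 200), (300, 400), (500, 600)])
        st_ = classify_isoform_status(m, three_exon_gene)
        assert st_.status == "known" and st_.reason == "matches_reference"

    def test_skipped_exon_is_new_intron(self, three_exon_gene):
        m = make_transcript("m", [(100, 200), (500, 600)])
        st_ = classify_isoform_status(m, three_exon_gene)
        assert st_.status == "novel" and st_.reason == "new_intron"

    def test_three_prime_shift_beyond_tolerance(self, three_exon_gene):
        m = make_transcript("m", [(100, 200), (300, 400), (500, 800)])
        st_ = classify_isoform_status(m, three_exon_gene)
        assert st_.reason == "changed_3prime_end"

    def test_three_prime_jitter_within_tolerance_stays_known(
        self, three_exon_gene
    ):
        m = make_transcript("m", [(100, 200), (300, 400), (500, 640)])
        assert classify_isoform_status(m, three_exon_gene).status == "known"

    def test_retained_intron_is_new_exon(self, three_exon_gene):
        m = make_transcript("m", [(100, 400), (500, 600)])
        st_ = classify_isoform_status(m, three_exon_gene)
        assert st_.reason == "new_exon"

    def test_member_of_novel_locus(self):
        m = make_transcript("m", [(0, 100)], source="isoseq")
        locus = GeneLocus("NG.chr1.1", [m], status="novel")
        assert classify_isoform_status(m, locus).reason == "novel_locus"


class TestMergeAndPipeline:
    def test_counting_fixture(self):
        """2 novel loci + 3 novel isoforms in known genes -> the updated
        annotation gains exactly 2 loci and 5 transcripts."""
        genes = [
            GeneLocus(
                g,
                [make_transcript(f"{g}.t", [(b, b + 200), (b + 500, b + 700),
                                            (b + 900, b + 1100)])],
            )
            for g, b in (("GA", 1000), ("GB", 10_000), ("GC", 50_000))
        ]
        reference = GenomeAnnotation(genes)
        cands = [
            # one skip variant per known gene -> 3 novel isoforms
            cand("n1", [(1000, 1200), (1900, 2100)], reads=3),
            cand("n2", [(10_000, 10_200), (10_900, 11_100)], reads=3),
            cand("n3", [(50_000, 50_200), (50_900, 51_100)], reads=3),
            # two isolated candidates -> 2 novel loci
            cand("nl1", [(20_000, 20_400)], reads=2),
            cand("nl2", [(30_000, 30_400)], reads=2),
        ]
        res = update_annotation(cands, JunctionSet(), reference)
        assert res.n_novel_loci == 2
        assert res.updated.n_loci() == reference.n_loci() + 2
        assert res.updated.n_transcripts() == reference.n_transcripts() + 5
        # novel isoform in a known locus follows the <chrom>.<n>.<m> shape
        new_ids = res.updated.transcript_ids() - reference.transcript_ids()
        assert "1.1.2" in new_ids

    def test_no_novel_representatives_is_identity(self, reference):
        cands = [cand("c", [(100, 200), (300, 400), (500, 600)], reads=2)]
        res = update_annotation(cands, JunctionSet(), reference)
        assert res.updated == reference

    def test_merge_skips_known_duplicates(self, reference):
        reps = []
        updated = merge_annotation(reference, reps, {}, [], {})
        assert updated == reference

    def test_pipeline_idempotence(self, small_annotation):
        cands = [
            FLNCIsoformCandidate(
                t.transcript_id + "_refeed",
                make_transcript(
                    t.transcript_id + "_refeed",
                    [(e.start, e.end) for e in t.exons],
                    chrom=t.chrom,
                    strand=t.strand,
                    source="isoseq",
                ),
                2,
                100.0,
            )
            for t in small_annotation.transcripts()
        ]
        res = update_annotation(cands, JunctionSet(), small_annotation)
        assert res.n_novel_isoforms == 0
        assert res.n_novel_loci == 0
        assert res.updated == small_annotation
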