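# Methods

This note records the models, rules and numerical choices behind each
module, what the synthetic generator does and does not emulate, and the
design decisions taken where reasonable alternatives existed.

## Coordinates and the interval model

All coordinates are internal 0-based half-open intervals; GFF3 I/O
converts to and from 1-based inclusive. Only `+`/`-` strands are
accepted — every downstream rule (overlap, splice-chain identity,
promoter orientation, 5′ vs 3′ splice-site labels) is strand-conditional,
so an unstranded record has no well-defined behaviour and is rejected at
parse time. A transcript is an ordered chain of disjoint exons; its
intron chain is the ordered list of gaps. Mono-exonic transcripts have an
empty chain and are accepted everywhere splice chains are consumed.

GFF3 reading is delegated to gffutils (in-memory database, ID/Parent
resolution); writing is done directly so the output is byte-deterministic
with records ordered by chromosome registry, locus start, then the
gene → mRNA → exon → UTR hierarchy. Reading back a written file
reconstructs the in-memory annotation field for field.

"Length" in every 20%-overlap rule means exonic length (sum of exon
sizes), not genomic span: span-based fractions would inflate overlap for
long-intron genes, and junction-level identity is what exonic overlap
reflects. The overlap fraction used for linking is relative to the
shorter model; candidates sharing at least 20% of the shorter's exonic
bases on the same strand are considered the same isoform group, strictly
less keeps them distinct.

## Isoform retention, collapse and classification

The four retention criteria are a disjunction; each candidate's decision
records which criteria fired. Criterion C3 quantifies over a candidate's
splice junctions, so a mono-exonic candidate satisfies it vacuously.
Criterion C4 ("all AS events annotated in the reference") is
operationalised as intron-level containment in the reference's intron
universe: an event-level formulation would require an event inventory of
the reference that the rule itself is meant to establish. The predicate
is isolated so an event-level variant can be substituted.

Collapse is single-linkage: overlap chains (a~b, b~c) merge even when
a and c are disjoint. The cluster representative is the member with the
most FLNC reads (ties: larger exonic length, then smallest id) and
carries the cluster's summed read count, so total read support is
conserved.

Locus assignment picks the known gene with the largest
fraction-of-shorter exonic overlap against the gene's exon union
(ties: more shared bases, then lexicographic gene id) when that fraction
reaches 20%; leftovers are clustered among themselves by the same rule
into novel loci named `NG.<chrom>.<k>`, numbered by leftmost start per
chromosome.

A model is a known isoform when some transcript already in the locus has
an identical intron chain and a 3′ terminus within the end tolerance
(default 50 bp — long-read 3′ ends jitter, and exact matching would call
essentially everything novel). Otherwise the reason is the first of:
new intron; new exonic sequence (> tolerance bases of exon outside the
union of the locus's annotated exons, counted only inside the envelope
of those exons — terminal extensions beyond the outermost annotated exon
are end differences, not new exons); changed 3′ end; novel locus.
Comparison is against *all* transcripts the locus already carries, not
only those tagged as original reference models: this makes the update
idempotent — feeding an updated annotation's own transcripts back yields
zero new records. Novel isoforms merged into known loci receive ids
`<chrom>.<locus rank>.<serial>` (the id shape conventional for
Iso-seq-derived transcripts); id collisions are disambiguated with a
logged suffix.

## AS event taxonomy

Events are found by comparing intron chains inside the span shared by
both models, so pure end-length differences are never events. The five
canonical types are:

- **exon skipping** — an intron of one model strictly contains a full
  exon of the other and both of its splice sites are splice sites of the
  other model (the flank condition stops mutually-exclusive structures
  being mis-called as skips);
- **intron retention** — an exon of one model covers an intron of the
  other plus flanking exonic sequence on both sides;
- **alt 5′/3′ splice site** — introns sharing exactly one boundary,
  labelled by transcription direction; the region between the two
  alternative boundaries must contain no complete exon of either model,
  otherwise the difference is a skip/MXE structure and the alt-site call
  is suppressed;
- **mutually exclusive exons** — internal exons, one per model,
  non-overlapping, with coinciding outer flanking splice sites.

Genome-wide counts deduplicate on (event type, variant region), so a
skipped exon seen in many isoform pairs counts once. Alternative
first/last exons and compound structures outside the five types are out
of scope; the full structure-code grammar of dedicated AS tools is not
reproduced.

## Negative-binomial differential engine

One simplified engine stands in for the dedicated count-based tools for
both isoform and peak matrices (both reduce to NB GLMs); exact numerical
parity with those tools is a non-goal. Stages:

1. **Size factors** — median-of-ratios: per-feature geometric means over
   samples (features with any zero excluded), per-sample factor = median
   ratio. A pseudo-reference fallback (geometric mean over positive
   entries) is available for sparse matrices and must be requested
   explicitly.
2. **Dispersion** — per feature, method of moments on normalised counts
   using the pooled within-group variance (so a true group effect does
   not inflate α), floored at 1e-8, then shrunk halfway toward the mean
   dispersion of the feature's expression decile. The halfway
   decile-trend shrinkage is a deliberate simplification of
   empirical-Bayes schemes; with 3 + 3 samples the raw moment estimate is
   very noisy and the trend term stabilises it.
3. **Wald test** — IRLS fit of the two-parameter log-link NB model with
   size-factor offsets, vectorised across features (closed-form 2×2
   weighted normal equations per iteration, convergence tolerance 1e-10,
   coefficients clipped at ±25 to survive all-zero groups); two-sided
   normal p-value on the group coefficient. All-zero features get p = 1
   and log2FC = 0. With n = 3 per group the Wald test is expected to be
   mildly anticonservative; measured type-I error at α = 0.05 on the
   generator's null is ≈ 0.06.
4. **FDR** — Benjamini–Hochberg step-up with enforced monotonicity,
   returned in input order.

The reported log2 fold change is the display value
log2((m₂ + 0.5)/(m₁ + 0.5)) of normalised group means — the 0.5
pseudo-count avoids infinities; the test itself uses the GLM estimate.
Isoform significance requires |FC| > 2 and FDR < 0.05, both directions.
Differential peaks require FDR < 0.05 and a nonzero fold in either
direction, reported as up/down by sign: the "enrichment greater than
zero" convention is read as nonzero enrichment either way, since both
up- and down-regulated peak sets are meaningful.

## Peak annotation and overlap testing

Classification is midpoint-based with global category priority
promoter > 5′ UTR > 3′ UTR > exon > intron > intergenic (an exon of any
gene beats an intron of any gene). The promoter window defaults to
TSS ± 3000 bp oriented by the gene's strand, the default of the common
peak-annotation tooling, and is configurable because published analyses
rarely state it. Peaks are strand-less; orientation always comes from
the gene. The assigned gene is the owner of the winning feature, ties
broken by TSS distance then gene id. Because every midpoint lands in
exactly one category, distribution counts always partition the input.

Gene-set overlap uses the exact hypergeometric upper tail
(equivalently one-sided Fisher), with odds ratio (a·d)/(b·c) and the
conventions +∞ / 0 / 1 for degenerate tables. The gene universe defaults
to the number of loci in the annotation in use; published overlap tests
often leave the universe unstated, and the p-value depends on it, so it
is an explicit argument. Genes are linked to peaks when a peak overlaps
the gene body or its promoter window by at least one base.

## Trait and qPCR statistics

The summary-statistic t-test defaults to Welch (the default of the
standard statistical environments); the pooled-variance form is an
option — with equal group sizes the t statistic is identical and only
df/p differ. Recomputing a published t from rounded mean ± SD summaries
cannot reproduce it exactly; agreement within 2% is the documented
expectation for 4-significant-digit inputs.

2^−ΔΔCt follows the Livak formulation: replicate Cts averaged per
sample, ΔCt = target − reference, ΔΔCt centred on the calibrator group's
mean ΔCt (exactly zero-mean in the calibrator by construction; the
calibrator's mean *relative expression* is not exactly 1 because
2^−ΔΔCt averages geometrically). Per-sample calibrator pairing and
primer-efficiency corrections are not supported.

## Synthetic study generator

The generator emulates the study design the analyses assume, with all
randomness derived from one seed (per-stage substreams make each
generator a pure function of the configuration regardless of call
order):

- **Reference annotation** — 60 genes over 3 chromosomes (`chr1`,
  `chr2`, `chrX`; the non-numeric name exercises id handling), packed
  left-to-right with 12–30 kb gaps so loci never overlap; exon counts
  Poisson with mean 6, exon lengths 80–300 bp, introns 0.2–2 kb; 60% of
  loci carry UTR records; secondary transcripts are splice variants of
  the primary, generated with the same perturbation machinery as the
  candidates, so reference loci themselves contain AS diversity.
- **FLNC candidates** — 150 per run; half are copies of reference
  transcripts with ≤ 20 bp 3′ jitter (within tolerance), half carry
  exactly one planted perturbation: an AS event from the mix (skip .35,
  retention .25, alt 5′ .15, alt 3′ .15, MXE .10) or, for 15% of novels,
  a 3′ shift of 100–300 bp. One event per candidate keeps classifier
  scoring unambiguous. Read counts are 1 + Poisson(2); PIDs
  normal(99, 0.8) clipped to [90, 100]. Truth status/reason is computed
  by direct set arithmetic against the locus's reference models, so
  coincidental matches (a perturbation reproducing an existing variant)
  are labelled correctly.
- **Junctions** — every true intron (reference and candidate) enters the
  short-read junction set independently with probability 0.9, emulating
  incomplete RNA-seq support.
- **Counts** — two groups of three samples, matching the study's 3 vs 3
  crossbred design; baselines log-normal(log 100, 1), NB dispersion 0.1,
  10% of features at ±2 log2 units (random sign), per-sample depth
  factors in [0.75, 1.3] so the normalisation stage is non-trivial.
- **Peaks** — 200 peaks with midpoints drawn from per-category base
  sets constructed by interval algebra with the same priority as the
  point classifier (the construction is the ground truth); the default
  placement mix (intergenic .50, intron .24, promoter .12, exon .08,
  UTRs .06) mirrors the typical genome-wide occupancy profile. Counts
  are NB over two conditions with two replicates each — the study design
  has one ChIP sample per condition, but the NB test needs replication,
  so the generator defaults to duplicates — with 20% of peaks carrying
  ±2 log2 enrichment.

The generator does **not** emulate read-level properties: no sequencing
errors, no alignment artefacts, no positional biases, no correlated
isoform structures within genes, no mixture of fragment lengths. Tests
passing on this synthetic data therefore certify the *logic* of each
stage (criteria, clustering, classification, calibration of the NB test
under its assumed model) — not robustness to real-data artefacts such as
misalignment near splice sites or PCR duplicates.

## Problem sizes and determinism

The shipped tests and the acceptance script use desk-scale sizes chosen
to give stable statistics at interactive runtimes: 2000 features × 3
seeds for calibration, 500 perturbation pairs for event recovery, the
full enumeration grid up to universe 30 for the hypergeometric check,
50 simulated annotations for round-trip identity. All stochastic checks
are seeded; the acceptance script derives per-stage seeds from its
`--seed` argument.

## Known limitations

- The NB Wald test is slightly anticonservative at n = 3 per group;
  consumers needing strict type-I control at small n should prefer the
  calibrated FDR-level guarantees (observed FDR stays below nominal ×2
  in the shipped recovery checks) over raw p-values.
- C4 retention is junction-level, not event-level (see above).
- The AS taxonomy omits alternative first/last exons; complex loci can
  produce compound differences outside the five types, which are simply
  not reported.
- Midpoint-based peak classification ignores peak width; a wide peak
  straddling a boundary is attributed to its midpoint's category.
- The overlap test treats gene sets as exchangeable draws from the
  universe; expression-dependent detection bias is not modelled.
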