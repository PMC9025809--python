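"""Annotate ChIP-seq peaks by genomic feature and test gene-set overlap.

Classifies peak midpoints into promoter / UTR / exon / intron /
intergenic, calls differential peaks from the two-condition counts, then
asks whether genes near differential peaks overlap genes with
differential isoforms more than chance (hypergeometric upper tail).
"""

from isoforge.differential import call_differential_peaks, differential_analysis
from isoforge.overlap import feature_distribution, gene_overlap_test, peaks_to_genes
from isoforge.simulate import SimulationConfig, simulate_workspace

ws = simulate_workspace(SimulationConfig(seed=1))
ann, peaks = ws["reference"], ws["peaks"]

counts, props = feature_distribution([p.location for p in peaks], ann)
print("peak distribution over genomic features:")
for cat, n in counts.items():
    print(f"  {cat:>16}: {n:4d}  ({100 * props[cat]:.1f}%)")

results = differential_analysis(ws["peak_counts"])
up, down = call_differential_peaks(results, max_fdr=0.05)
diff_ids = {r.feature_id for r in up + down}
print(f"\n{len(diff_ids)} differential peaks ({len(up)} up, {len(down)} down)")

peak_genes = peaks_to_genes(
    [p for p in peaks if p.peak_id in diff_ids], ann
)
# stand-in DEI gene set: genes on the first chromosome
dei_genes = {g for g, L in ann.loci.items() if L.chrom == "chr1"}
test = gene_overlap_test(peak_genes, dei_genes, universe=ann.n_loci())
print(f"genes near differential peaks: {len(peak_genes)}; "
      f"DEI genes: {len(dei_genes)}; overlap: {test.overlap}")
print(f"hypergeometric P(X >= {test.overlap}) = {test.p_value:.3g}, "
      f"odds ratio {test.odds_ratio:.2f}")
# p below 0.05 would say the shared genes are too many to be chance.
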