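"""Materialise a complete synthetic study workspace on disk.

Generates every input the pipeline consumes — reference GFF3, FLNC
candidate BED12 + support sidecar, short-read junction BED, isoform and
peak count matrices with group labels — plus the ground-truth tables,
all reproducible from the seed.
"""

from isoforge.simulate import SimulationConfig, simulate_workspace

cfg = SimulationConfig(seed=1)
ws = simulate_workspace(cfg, outdir="scratch/workspace")

print(f"reference: {ws['reference'].n_loci()} loci, "
      f"{ws['reference'].n_transcripts()} transcripts")
print(f"candidates: {len(ws['candidates'])} "
      f"({(ws['candidate_truth'].true_status == 'novel').sum()} truly novel)")
print(f"junctions: {len(ws['junctions'])} supported introns")
print(f"isoform counts: {ws['isoform_counts'].counts.shape}")
print(f"peaks: {len(ws['peaks'])}")
print("files written under scratch/workspace/")
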