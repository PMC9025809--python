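"""Classify alternative-splicing events between isoforms of each locus.

Counts exon skipping, intron retention, alternative 5'/3' splice sites
and mutually exclusive exons across a synthetic annotation, the same
event census usually reported genome-wide for pooled long-read data.
"""

from collections import Counter

from isoforge.events import locus_events
from isoforge.simulate import SimulationConfig, simulate_reference_annotation

ann = simulate_reference_annotation(SimulationConfig(seed=1))

census: Counter = Counter()
total = 0
for locus in ann.loci.values():
    events, n = locus_events(locus)
    total += n
    census.update(e.event_type for e in events)

print(f"{total} alternative-splicing events across {ann.n_loci()} loci")
for etype, n in census.most_common():
    print(f"  {etype:>20}: {n}")
# Each count is a deduplicated (event type, variant region) pair: the
# same skipped exon seen in several isoform pairs is counted once.
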