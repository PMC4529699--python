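"""Simulate a small-RNA library and assign every read to an RNA class.

Builds the toy genome with its five annotation sources, draws one cell
library, runs the hierarchical featuretype cascade on the reads'
equal-best-score alignments, and prints the class composition next to
the simulated truth.
"""

import collections

from exosmallrna import annotation_io as aio
from exosmallrna import feature_assignment as fa
from exosmallrna import synthetic_data as sd

config = sd.SimulationConfig(seed=42, n_reads=5000)
toy, samples = sd.simulate_reads(config)
index = aio.build_index(toy.all_records())

sample = samples[0]  # an adipose-MSC cell library
calls = fa.assign_all(sample.alignment_sets(), index)

truth = collections.Counter(r.rna_class for r in sample.reads)
called = collections.Counter(fa.reporting_class(c.featuretype) for c in calls)

print(f"sample {sample.name}: {len(calls)} reads assigned")
print(f"{'class':<16}{'called':>8}{'truth':>8}")
for cls in sorted(set(truth) | set(called)):
    print(f"{cls:<16}{called.get(cls, 0):>8}{truth.get(cls, 0):>8}")

agree = sum(fa.reporting_class(c.featuretype) == truth_cls
            for c, truth_cls in zip(calls, (r.rna_class for r in sorted(sample.reads, key=lambda r: r.read_id))))
print(f"\nper-read agreement with truth: {agree / len(calls):.1%}")
print("Each read lands on one RNA class; multi-mapping repeat reads and the")
print("planted miRNA/repeat overlaps are resolved by the rule cascade.")
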