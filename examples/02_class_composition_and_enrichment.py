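"""Class composition and cell-vs-exosome differential representation.

Runs the default two-condition design (3 cell + 3 exosome libraries),
tabulates RNA-class fractions, and tests each class for differential
representation in exosomes with the common-dispersion NB exact test.
The simulated exosomes carry a four-fold enriched tRNA class.
"""

from exosmallrna import annotation_io as aio
from exosmallrna import feature_assignment as fa
from exosmallrna import quantification as q
from exosmallrna import stats
from exosmallrna import synthetic_data as sd

config = sd.SimulationConfig(seed=42, n_reads=10_000)
toy, samples = sd.simulate_reads(config)
index = aio.build_index(toy.all_records())
calls_by = {s.name: fa.assign_all(s.alignment_sets(), index) for s in samples}

fractions = q.class_fractions(calls_by)
print("RNA-class fractions (per sample):")
print((fractions * 100).round(1).to_string())

counts = q.class_counts(calls_by)
groups = {s.name: s.condition for s in samples}
phi = stats.estimate_common_dispersion(counts, groups)
result = stats.exact_test_nb(counts, groups, phi, reference_group="cell")
print(f"\ncommon dispersion phi = {phi:.4f}")
print("\nclasses ordered by logFC (exosome vs cell):")
print(result.sort_values("logFC", ascending=False).round(4).to_string())
print("\nA positive logFC marks a class overrepresented in exosomes; the")
print("tRNA class shows logFC ~ 2 (the planted 4-fold enrichment) at tiny FDR,")
print("while the remaining classes only shift by the compositional rescaling.")
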