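"""Independent brute-force interpreter of the featuretype rule cascade.

Written directly from the prose rules, operating on plain featuretype
label sets, as an oracle for the production implementation.  Kept free of
any package imports beyond the label constants.
"""

from __future__ import annotations


def oracle_resolve(read_length: int, per_alignment_sets: list[frozenset[str]]) -> str:
    union = frozenset().union(*per_alignment_sets) if per_alignment_sets else frozenset()
    if not union:
        return "Unannotated"
    if len(union) == 1:
        return next(iter(union))

    candidates = set(union)
    if read_length > 25:
        candidates -= {"miRNA_processed"}
    else:
        candidates -= {"miRNA_premature"}
    if read_length > 32:
        candidates -= {"piRNA"}
    if len(candidates) == 1:
        return next(iter(candidates))
    if len(candidates) == 2 and "repeat" in candidates:
        non_repeat = [f for f in candidates if f != "repeat"]
        return non_repeat[0]
    if len(per_alignment_sets) >= 2:
        candidates = {
            f for f in candidates
            if sum(1 for s in per_alignment_sets if f in s) >= 2
        }
    if len(candidates) == 1:
        return next(iter(candidates))
    return "Ambiguous"
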