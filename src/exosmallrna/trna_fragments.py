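"""Classification of tRNA-derived reads into halves, full-length and other
fragments, plus anticodon profiles and top-fragment lists.

Exosomes preferentially package ~33-nt 5' halves of abundant tRNAs
(notably Glu-CTC and Gly-GCC), while cells retain mostly full-length
(~70-75 nt) molecules.  The classifier anchors halves at the gene ends:
a fragment is a 5' half when it starts within ``five_prime_anchor`` bases
of the gene's 5' end and its length falls inside the half-length window;
3' halves mirror this at the 3' end; reads covering at least
``full_cov`` of the gene are full-length; everything else is "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import AnnotationRecord
from .read_processing import Alignment

FRAGMENT_CLASSES = ("five_prime_half", "three_prime_half", "full_length", "other")

DEFAULT_HALF_LEN = (28, 36)
DEFAULT_ANCHOR = 3
DEFAULT_FULL_COV = 0.9


@dataclass(frozen=True)
class FragmentCall:
    read_id: str
    gene_id: str
    anticodon: str
    fragment_class: str
    start_offset: int
    end_offset: int


def classify_fragment(
    alignment: Alignment,
    gene: AnnotationRecord,
    five_prime_anchor: int = DEFAULT_ANCHOR,
    half_len: tuple[int, int] = DEFAULT_HALF_LEN,
    full_cov: float = DEFAULT_FULL_COV,
) -> FragmentCall:
    """Classify one tRNA-resolved alignment relative to its gene.

    Offsets are 0-based in gene orientation (5'->3' of the tRNA), clipped
    to the gene body.
    """
    iv = alignment.interval
    glen = gene.end - gene.start
    lo = max(iv.start, gene.start) - gene.start
    hi = min(iv.end, gene.end) - gene.start
    if gene.strand == "-":
        lo, hi = glen - hi, glen - lo
    length = hi - lo

    min_half, max_half = half_len
    if (hi - lo) / glen >= full_cov:
        frag_class = "full_length"
    elif lo <= five_prime_anchor and min_half <= length <= max_half:
        frag_class = "five_prime_half"
    elif hi >= glen - five_prime_anchor and min_half <= length <= max_half:
        frag_class = "three_prime_half"
    else:
        frag_class = "other"
    return FragmentCall(
        read_id=alignment.read_id,
        gene_id=gene.record_id,
        anticodon=gene.metadata.get("anticodon", "NA"),
        fragment_class=frag_class,
        start_offset=lo,
        end_offset=hi,
    )


def fragment_class_shares(calls: Sequence[FragmentCall]) -> pd.Series:
    """Proportion of each fragment class among the given calls."""
    counts = pd.Series([c.fragment_class for c in calls]).value_counts()
    counts = counts.reindex(FRAGMENT_CLASSES, fill_value=0)
    total = counts.sum()
    if total == 0:
        return counts.astype(float)
    return counts / total


def anticodon_profile(
    calls_by_sample: Mapping[str, Sequence[FragmentCall]]
) -> pd.DataFrame:
    """Per-sample distribution over anticodons (columns sum to 1)."""
    frames = {}
    for sample, calls in calls_by_sample.items():
        counts = pd.Series([c.anticodon for c in calls]).value_counts()
        frames[sample] = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(frames).fillna(0.0).rename_axis("anticodon").sort_index()


def top_fragments(
    per_sample_sequence_counts: Mapping[str, Mapping[str, int]], n: int = 20
) -> list[str]:
    """Nonredundant union of each sample's n most abundant tRNA fragment sequences.

    Within a sample, ranking is by count descending with ties broken by
    sequence (lexicographic).  The union is returned sorted for
    determinism.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    union: set[str] = set()
    for counts in per_sample_sequence_counts.values():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        union.update(seq for seq, _ in ranked[:n])
    return sorted(union)


def write_fragment_tsv(calls: Sequence[FragmentCall], path) -> None:
    with open(path, "w") as out:
        out.write("read_id\tgene_id\tanticodon\tfragment_class\tstart_offset\tend_offset\n")
        for c in calls:
            out.write(
                f"{c.read_id}\t{c.gene_id}\t{c.anticodon}\t{c.fragment_class}\t"
                f"{c.start_offset}\t{c.end_offset}\n"
            )


def write_fasta(sequences: Sequence[str], path, prefix: str = "frag") -> None:
    """Write fragment sequences as FASTA queries for the antisense search."""
    with open(path, "w") as out:
        for i, seq in enumerate(sequences, start=1):
            out.write(f">{prefix}{i}\n{seq}\n")
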