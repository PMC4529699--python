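"""Hierarchical featuretype assignment of multi-mapped small-RNA reads.

Each read carries one or more equal-best-score alignments; each alignment
overlaps zero or more annotation records.  The union of overlapped
featuretypes is disambiguated by a fixed rule cascade:

0. empty union                      -> "Unannotated"
1. a single featuretype             -> assign it
2. read length > 25 nt eliminates "miRNA_processed",
   otherwise "miRNA_premature" is eliminated
3. read length > 32 nt eliminates "piRNA"
4. single featuretype left          -> assign it
5. exactly two left, one a repeat   -> assign the non-repeat
6. with >=2 alignments, eliminate featuretypes indicated by only one
   alignment
7. single featuretype left          -> assign it
8. otherwise                        -> "Ambiguous"

GENCODE subtypes (snoRNA, rRNA, snRNA, miscRNA, ...) count as distinct
featuretypes throughout, so the cascade preserves the RNA classes used
for composition reporting.  Resolved calls are refined to the miRNA name,
tRNA anticodon (+ amino acid), repeat family or gene type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import AnnotationRecord, FeatureIndex
from .read_processing import AlignmentSet

AMBIGUOUS = "Ambiguous"
UNANNOTATED = "Unannotated"


@dataclass
class FeatureCall:
    read_id: str
    read_length: int
    featuretype: str
    refined_label: str | None = None
    supporting_records: list[str] = field(default_factory=list)
    n_alignments: int = 0

    @property
    def resolved(self) -> bool:
        return self.featuretype not in (AMBIGUOUS, UNANNOTATED)


def overlapping_featuretypes(
    alignment_set: AlignmentSet, index: FeatureIndex, stranded: bool = True
) -> list[list[AnnotationRecord]]:
    """Per-alignment lists of overlapping annotation records."""
    return [index.query(aln.interval, stranded=stranded) for aln in alignment_set.alignments]


def resolve_featuretype(
    read_length: int, per_alignment_records: list[list[AnnotationRecord]]
) -> tuple[str, list[AnnotationRecord]]:
    """Run the disambiguation cascade.

    Returns the winning cascade featuretype label (see
    :meth:`AnnotationRecord.cascade_key`) — or "Ambiguous"/"Unannotated" —
    together with the records supporting the call.
    """
    per_alignment_sets = [
        {rec.cascade_key() for rec in records} for records in per_alignment_records
    ]
    union: set[str] = set().union(*per_alignment_sets) if per_alignment_sets else set()

    def supporting(ftype: str) -> list[AnnotationRecord]:
        seen: dict[str, AnnotationRecord] = {}
        for records in per_alignment_records:
            for rec in records:
                if rec.cascade_key() == ftype:
                    seen[rec.record_id] = rec
        return [seen[k] for k in sorted(seen)]

    # step 0/1
    if not union:
        return UNANNOTATED, []
    if len(union) == 1:
        (ftype,) = union
        return ftype, supporting(ftype)

    remaining = set(union)
    # step 2: length rule for mature vs precursor miRNA
    if read_length > 25:
        remaining.discard("miRNA_processed")
    else:
        remaining.discard("miRNA_premature")
    # step 3: long reads cannot be piRNA
    if read_length > 32:
        remaining.discard("piRNA")
    # step 4
    if len(remaining) == 1:
        (ftype,) = remaining
        return ftype, supporting(ftype)
    # step 5: prefer the unique non-repeat between exactly two candidates
    if len(remaining) == 2 and "repeat" in remaining:
        (ftype,) = remaining - {"repeat"}
        return ftype, supporting(ftype)
    # step 6: with multiple alignments, drop featuretypes seen by only one
    if len(per_alignment_sets) >= 2:
        support_counts = {
            ftype: sum(1 for s in per_alignment_sets if ftype in s) for ftype in remaining
        }
        remaining = {f for f, c in support_counts.items() if c >= 2}
    # step 7/8
    if len(remaining) == 1:
        (ftype,) = remaining
        return ftype, supporting(ftype)
    return AMBIGUOUS, []


def refine_call(
    featuretype: str, records: list[AnnotationRecord]
) -> str | None:
    """Refined label for a resolved call; None for Ambiguous/Unannotated.

    miRNA calls resolve to the miRNA name, tRNA calls to
    "tRNA-<aa>-<anticodon>", repeat calls to the repeat family and GENCODE
    calls to the gene type.  Disagreement among supporting records yields
    "multi:<sorted labels>".
    """
    if featuretype in (AMBIGUOUS, UNANNOTATED) or not records:
        return None
    labels = set()
    for rec in records:
        if rec.featuretype in ("miRNA_processed", "miRNA_premature"):
            labels.add(rec.metadata.get("mirna_name", rec.name))
        elif rec.featuretype == "tRNA":
            labels.add(f"tRNA-{rec.metadata.get('aa', 'NA')}-{rec.metadata.get('anticodon', 'NA')}")
        elif rec.featuretype == "repeat":
            labels.add(rec.metadata.get("family", rec.name))
        elif rec.featuretype == "gencode_small":
            labels.add(rec.metadata.get("gene_type", "NA"))
        else:
            labels.add(rec.name)
    if len(labels) == 1:
        return labels.pop()
    return "multi:" + ",".join(sorted(labels))


def reporting_class(featuretype: str) -> str:
    """Human-facing RNA class for a cascade label.

    GENCODE subtype labels collapse to their gene type (snoRNA, rRNA, ...)
    and the miRNA labels keep their processed/premature distinction.
    """
    if featuretype.startswith("gencode_small:"):
        return featuretype.split(":", 1)[1]
    return featuretype


def assign_read(
    alignment_set: AlignmentSet, index: FeatureIndex, stranded: bool = True
) -> FeatureCall:
    """Assign one read: overlap query, cascade, refinement."""
    per_alignment = overlapping_featuretypes(alignment_set, index, stranded=stranded)
    ftype, records = resolve_featuretype(alignment_set.read.length, per_alignment)
    return FeatureCall(
        read_id=alignment_set.read.read_id,
        read_length=alignment_set.read.length,
        featuretype=ftype,
        refined_label=refine_call(ftype, records),
        supporting_records=[rec.record_id for rec in records],
        n_alignments=len(alignment_set.alignments),
    )


def assign_all(
    alignment_sets: dict[str, AlignmentSet], index: FeatureIndex, stranded: bool = True
) -> list[FeatureCall]:
    """Assign every read, in deterministic read-id order."""
    return [assign_read(alignment_sets[rid], index, stranded=stranded) for rid in sorted(alignment_sets)]


def write_calls_tsv(calls: list[FeatureCall], path) -> None:
    with open(path, "w") as out:
        out.write("read_id\tlength\tfeaturetype\trefined_label\tn_alignments\n")
        for call in calls:
            out.write(
                f"{call.read_id}\t{call.read_length}\t{reporting_class(call.featuretype)}\t"
                f"{call.refined_label or ''}\t{call.n_alignments}\n"
            )
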