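"""Loading, filtering and indexing of small-RNA genome annotations.

Five annotation sources feed the read-assignment stage:

* GENCODE-style small genes (snoRNA, rRNA, snRNA, miscRNA, ...) kept only
  when their spliced length is at most ``max_total_length`` (120 nt by
  default) and their gene type is outside an exclusion set,
* miRBase-style precursor (``primary_transcript``) and mature (``miRNA``)
  annotations,
* tRNA genes with anticodon/amino-acid metadata,
* piRNA intervals collapsed transitively into clusters,
* RepeatMasker-style repeat copies with their family.

All coordinates are held 0-based half-open internally; GTF/GFF3 input
(1-based inclusive) is converted on read.  Overlap queries are same-strand
by default, with an opt-in strand-agnostic mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: closed featuretype vocabulary
FEATURETYPES = frozenset(
    {"gencode_small", "miRNA_premature", "miRNA_processed", "tRNA", "piRNA", "repeat"}
)

#: GENCODE gene types removed before read assignment
DEFAULT_EXCLUDED_GENE_TYPES = frozenset({"sense_intronic", "sense_overlapping", "miRNA"})

# one-letter-agnostic map anticodon -> amino acid (standard genetic code on
# the codon read off the anticodon)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CODON_TABLE = {
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu",
    "CTT": "Leu", "CTC": "Leu", "CTA": "Leu", "CTG": "Leu",
    "ATT": "Ile", "ATC": "Ile", "ATA": "Ile", "ATG": "Met",
    "GTT": "Val", "GTC": "Val", "GTA": "Val", "GTG": "Val",
    "TCT": "Ser", "TCC": "Ser", "TCA": "Ser", "TCG": "Ser",
    "CCT": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro",
    "ACT": "Thr", "ACC": "Thr", "ACA": "Thr", "ACG": "Thr",
    "GCT": "Ala", "GCC": "Ala", "GCA": "Ala", "GCG": "Ala",
    "TAT": "Tyr", "TAC": "Tyr", "TAA": "Stop", "TAG": "Stop",
    "CAT": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "AAT": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "GAT": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "TGT": "Cys", "TGC": "Cys", "TGA": "Stop", "TGG": "Trp",
    "CGT": "Arg", "CGC": "Arg", "CGA": "Arg", "CGG": "Arg",
    "AGT": "Ser", "AGC": "Ser", "AGA": "Arg", "AGG": "Arg",
    "GGT": "Gly", "GGC": "Gly", "GGA": "Gly", "GGG": "Gly",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_to_aa(anticodon: str) -> str:
    """Amino acid decoded by a tRNA with the given anticodon (e.g. CTC -> Glu)."""
    codon = reverse_complement(anticodon.upper())
    return CODON_TABLE.get(codon, "NA")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotationRecord:
    """One annotated feature: a set of intervals tagged with a featuretype.

    ``metadata`` carries the refinement labels used downstream: miRNA name
    and arm, tRNA anticodon and amino acid, repeat family, GENCODE gene
    type.
    """

    record_id: str
    name: str
    featuretype: str
    intervals: list[GenomicInterval]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.featuretype not in FEATURETYPES:
            raise AnnotationError(f"unknown featuretype {self.featuretype!r}")
        if not self.intervals:
            raise AnnotationError(f"record {self.record_id} has no intervals")
        chroms = {iv.chrom for iv in self.intervals}
        strands = {iv.strand for iv in self.intervals}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"record {self.record_id} spans multiple chroms/strands"
            )

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.intervals)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.intervals)

    @property
    def total_length(self) -> int:
        """Spliced length: sum of interval lengths."""
        return sum(len(iv) for iv in self.intervals)

    def cascade_key(self) -> str:
        """Featuretype label used by the assignment cascade.

        GENCODE subtypes (snoRNA, rRNA, ...) are distinct labels so that a
        read over, say, a snoRNA and an rRNA is not treated as a single
        class; the other featuretypes map to themselves.
        """
        if self.featuretype == "gencode_small":
            return f"gencode_small:{self.metadata.get('gene_type', 'NA')}"
        return self.featuretype


# ---------------------------------------------------------------------------
# GTF / GFF3 attribute parsing


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse a column-9 attribute string of either GTF or GFF3 dialect."""
    attrs: dict[str, str] = {}
    attr_field = attr_field.strip()
    if "=" in attr_field.split(";")[0] and '"' not in attr_field.split(";")[0]:
        # GFF3: key=value;key=value
        for part in attr_field.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    else:
        # GTF: key "value"; key "value";
        for part in attr_field.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


def _iter_gff_lines(path: str | Path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}: malformed GTF/GFF line {lineno}")
            chrom, source, ftype, start, end, score, strand, frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: non-numeric coordinates on line {lineno}"
                ) from exc
            yield lineno, chrom, ftype, start_i - 1, end_i, strand, _parse_attributes(attrs)


# ---------------------------------------------------------------------------
# Loaders


def load_gencode(
    gtf_path: str | Path,
    max_total_length: int = 120,
    excluded_gene_types: Iterable[str] = DEFAULT_EXCLUDED_GENE_TYPES,
) -> list[AnnotationRecord]:
    """Load GENCODE-style small genes.

    Transcripts whose spliced (summed-exon) length exceeds
    ``max_total_length`` are dropped, as are genes of an excluded type
    (by default sense_intronic, sense_overlapping and miRNA — the latter
    because miRNAs come from the dedicated miRBase source).  One record is
    emitted per gene, carrying the union of its retained transcripts'
    exons; a gene with no retained transcript is excluded.
    """
    excluded = set(excluded_gene_types)
    # transcript_id -> (gene_id, gene_name, gene_type, [exons])
    transcripts: dict[str, dict] = {}
    for lineno, chrom, ftype, start, end, strand, attrs in _iter_gff_lines(gtf_path):
        if ftype != "exon":
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            logger.warning("%s line %d: exon without transcript_id, skipped", gtf_path, lineno)
            continue
        if "gene_type" not in attrs:
            logger.warning("%s line %d: missing gene_type attribute, record skipped", gtf_path, lineno)
            continue
        info = transcripts.setdefault(
            tid,
            {
                "gene_id": attrs.get("gene_id", tid),
                "gene_name": attrs.get("gene_name", attrs.get("gene_id", tid)),
                "gene_type": attrs["gene_type"],
                "exons": [],
            },
        )
        info["exons"].append(GenomicInterval(chrom, start, end, strand))

    genes: dict[str, dict] = {}
    for tid, info in transcripts.items():
        if info["gene_type"] in excluded:
            continue
        if sum(len(iv) for iv in info["exons"]) > max_total_length:
            continue
        gene = genes.setdefault(
            info["gene_id"],
            {"name": info["gene_name"], "gene_type": info["gene_type"], "exons": []},
        )
        gene["exons"].extend(info["exons"])

    records = []
    for gene_id in sorted(genes):
        gene = genes[gene_id]
        exons = sorted(set(gene["exons"]))
        records.append(
            AnnotationRecord(
                record_id=gene_id,
                name=gene["name"],
                featuretype="gencode_small",
                intervals=exons,
                metadata={"gene_type": gene["gene_type"]},
            )
        )
    return records


def _mirna_arm(name: str) -> str:
    lowered = name.lower()
    if lowered.endswith("-5p"):
        return "5p"
    if lowered.endswith("-3p"):
        return "3p"
    return "NA"


def load_mirbase(gff_path: str | Path) -> list[AnnotationRecord]:
    """Load miRBase-dialect GFF3: precursors and mature miRNAs.

    ``miRNA_primary_transcript`` (or ``primary_transcript``) features become
    ``miRNA_premature`` records; ``miRNA`` features become
    ``miRNA_processed`` records carrying the mature name and arm.  A mature
    feature without a resolvable parent precursor is kept with a warning.
    """
    records: list[AnnotationRecord] = []
    primary_ids: set[str] = set()
    matures = []
    for lineno, chrom, ftype, start, end, strand, attrs in _iter_gff_lines(gff_path):
        rec_id = attrs.get("ID", f"line{lineno}")
        name = attrs.get("Name", rec_id)
        iv = GenomicInterval(chrom, start, end, strand)
        if ftype in ("miRNA_primary_transcript", "primary_transcript"):
            primary_ids.add(rec_id)
            records.append(
                AnnotationRecord(rec_id, name, "miRNA_premature", [iv], {"mirna_name": name})
            )
        elif ftype == "miRNA":
            matures.append((rec_id, name, iv, attrs.get("Derives_from")))
    for rec_id, name, iv, parent in matures:
        if parent is not None and parent not in primary_ids:
            logger.warning("mature miRNA %s: parent %s not found, kept", name, parent)
        records.append(
            AnnotationRecord(
                rec_id,
                name,
                "miRNA_processed",
                [iv],
                {"mirna_name": name, "arm": _mirna_arm(name)},
            )
        )
    return records


def _parse_bed6(path: str | Path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}: BED6 line {lineno} has <6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            yield chrom, int(start), int(end), name, strand


def load_trna(
    bed_path: str | Path, metadata_table: Mapping[str, Mapping[str, str]] | str | Path
) -> list[AnnotationRecord]:
    """Load tRNA genes (BED6) with anticodon metadata.

    ``metadata_table`` maps gene id -> {"anticodon": ..., "aa": ...}; it may
    also be a path to a TSV with columns gene_id, anticodon[, aa].  Genes
    missing from the table get anticodon "NA" with a warning.
    """
    if not isinstance(metadata_table, Mapping):
        table: dict[str, dict[str, str]] = {}
        with open(metadata_table) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                entry = {"anticodon": fields[1]}
                if len(fields) > 2:
                    entry["aa"] = fields[2]
                table[fields[0]] = entry
        metadata_table = table

    records = []
    for chrom, start, end, name, strand in _parse_bed6(bed_path):
        meta_row = metadata_table.get(name)
        if meta_row is None:
            logger.warning("tRNA gene %s missing from metadata table; anticodon=NA", name)
            anticodon, aa = "NA", "NA"
        else:
            anticodon = meta_row["anticodon"]
            aa = meta_row.get("aa") or anticodon_to_aa(anticodon)
        records.append(
            AnnotationRecord(
                record_id=name,
                name=name,
                featuretype="tRNA",
                intervals=[GenomicInterval(chrom, start, end, strand)],
                metadata={"anticodon": anticodon, "aa": aa},
            )
        )
    return records


def collapse_intervals(
    intervals: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge same-chrom/strand intervals that overlap by >=1 base, transitively."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.strand, i.start, i.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and merged[-1].strand == iv.strand
            and iv.start < merged[-1].end
        ):
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), last.strand
            )
        else:
            merged.append(iv)
    return merged


def load_pirna(bed_path: str | Path) -> list[AnnotationRecord]:
    """Load piRNA intervals, collapsing overlapping annotations into clusters."""
    raw = [
        GenomicInterval(chrom, start, end, strand)
        for chrom, start, end, _name, strand in _parse_bed6(bed_path)
    ]
    clusters = collapse_intervals(raw)
    return [
        AnnotationRecord(
            record_id=f"piRNA_cluster_{i + 1}",
            name=f"piRNA_cluster_{i + 1}",
            featuretype="piRNA",
            intervals=[iv],
            metadata={},
        )
        for i, iv in enumerate(clusters)
    ]


def load_repeats(table_path: str | Path) -> list[AnnotationRecord]:
    """Load a RepeatMasker-style TSV: name, class/family, chrom, start, end, strand."""
    records = []
    with open(table_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                logger.warning("%s line %d: malformed repeat row, skipped", table_path, lineno)
                continue
            name, family, chrom, start, end, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except (ValueError, AnnotationError):
                logger.warning("%s line %d: malformed repeat row, skipped", table_path, lineno)
                continue
            records.append(
                AnnotationRecord(
                    record_id=f"{name}_{chrom}_{start}",
                    name=name,
                    featuretype="repeat",
                    intervals=[iv],
                    metadata={"family": family},
                )
            )
    return records


# ---------------------------------------------------------------------------
# Index


class FeatureIndex:
    """Per-chromosome, per-strand interval index over AnnotationRecords."""

    def __init__(self, records: Iterable[AnnotationRecord]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.records: list[AnnotationRecord] = list(records)
        for rec in self.records:
            for iv in rec.intervals:
                self._trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
                    iv.start, iv.end, rec
                )

    def query(
        self, interval: GenomicInterval, stranded: bool = True
    ) -> list[AnnotationRecord]:
        """Records overlapping ``interval`` by >=1 base.

        Same-strand only unless ``stranded=False``.  Deterministic order
        (record_id); each record reported once even if several of its
        intervals overlap.
        """
        strands = [interval.strand] if stranded else ["+", "-"]
        hits: dict[str, AnnotationRecord] = {}
        for strand in strands:
            tree = self._trees.get((interval.chrom, strand))
            if tree is None:
                continue
            for node in tree.overlap(interval.start, interval.end):
                hits[node.data.record_id] = node.data
        return [hits[k] for k in sorted(hits)]


def build_index(records: Iterable[AnnotationRecord]) -> FeatureIndex:
    return FeatureIndex(records)


# ---------------------------------------------------------------------------
# Unified annotation TSV round-trip

_TSV_HEADER = ["record_id", "name", "featuretype", "chrom", "strand", "intervals", "metadata"]


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_TSV_HEADER) + "\n")
        for rec in records:
            ivs = ",".join(f"{iv.start}-{iv.end}" for iv in rec.intervals)
            meta = ";".join(f"{k}={v}" for k, v in sorted(rec.metadata.items()))
            out.write(
                "\t".join(
                    [rec.record_id, rec.name, rec.featuretype, rec.chrom, rec.strand, ivs, meta]
                )
                + "\n"
            )


def read_annotation_tsv(path: str | Path) -> list[AnnotationRecord]:
    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise AnnotationError(f"{path}: unexpected annotation TSV header")
        for line in handle:
            rec_id, name, ftype, chrom, strand, ivs, meta = line.rstrip("\n").split("\t")
            intervals = []
            for span in ivs.split(","):
                start, _, end = span.partition("-")
                intervals.append(GenomicInterval(chrom, int(start), int(end), strand))
            metadata = {}
            if meta:
                for pair in meta.split(";"):
                    key, _, value = pair.partition("=")
                    metadata[key] = value
            records.append(AnnotationRecord(rec_id, name, ftype, intervals, metadata))
    return records
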