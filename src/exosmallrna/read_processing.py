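"""3' adapter trimming and best-score alignment ingestion.

Production inputs are FASTQ reads with a ligated 3' adapter, and SAM/BAM
alignments reported with up to 50 valid placements per read.  Only a
read's equal-best-score alignments move on to feature assignment.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .annotation_io import GenomicInterval

logger = logging.getLogger(__name__)

MAX_ALIGNMENTS = 50


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    read_id: str
    interval: GenomicInterval
    score: float
    n_mismatches: int = 0


@dataclass
class AlignmentSet:
    """One read plus its equal-best-score alignments (possibly none)."""

    read: TrimmedRead
    alignments: list[Alignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.alignments) > MAX_ALIGNMENTS:
            raise ValueError(f"read {self.read.read_id}: >{MAX_ALIGNMENTS} alignments")
        scores = {a.score for a in self.alignments}
        if len(scores) > 1:
            raise ValueError(
                f"read {self.read.read_id}: alignments do not share the best score"
            )


def find_adapter(
    sequence: str,
    adapter_seq: str,
    min_overlap: int = 12,
    max_error_rate: float = 0.25,
) -> int | None:
    """Locate the best 3' adapter occurrence; return the cut position.

    A candidate at read position ``i`` aligns the adapter prefix of length
    ``min(len(adapter), len(read) - i)`` against the read suffix starting
    at ``i``.  Candidates need at least ``min_overlap`` aligned bases and a
    mismatch fraction of at most ``max_error_rate``.  The best candidate
    maximizes matched bases; ties go to the longer overlap, then the
    leftmost position.  Everything from the cut position on (the adapter
    and any read-through beyond it) is removed.
    """
    if not adapter_seq:
        raise ValueError("adapter sequence must be non-empty")
    n, m = len(sequence), len(adapter_seq)
    best: tuple[int, int, int] | None = None  # (matches, overlap, -i)
    best_i: int | None = None
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        segment = sequence[i : i + overlap]
        matches = sum(a == b for a, b in zip(segment, adapter_seq))
        mismatches = overlap - matches
        if mismatches > max_error_rate * overlap:
            continue
        key = (matches, overlap, -i)
        if best is None or key > best:
            best = key
            best_i = i
    return best_i


def trim_adapter(
    read: TrimmedRead,
    adapter_seq: str,
    min_overlap: int = 12,
    max_error_rate: float = 0.25,
) -> TrimmedRead | None:
    """Remove the 3' adapter from a read; ``None`` marks an empty insert.

    Reads without an acceptable adapter occurrence are returned unchanged.
    """
    cut = find_adapter(read.sequence, adapter_seq, min_overlap, max_error_rate)
    if cut is None:
        return read
    if cut == 0:
        return None
    return TrimmedRead(read.read_id, read.sequence[:cut])


@dataclass
class TrimReport:
    reads_in: int = 0
    reads_trimmed: int = 0
    reads_discarded_empty: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("reads_in\treads_trimmed\treads_discarded_empty\n")
            out.write(f"{self.reads_in}\t{self.reads_trimmed}\t{self.reads_discarded_empty}\n")


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path):
    """Yield (read_id, sequence, quality) records from a FASTQ file."""
    with _open_maybe_gzip(path) as handle:
        while True:
            header = handle.readline().rstrip("\n")
            if not header:
                return
            seq = handle.readline().rstrip("\n")
            handle.readline()
            qual = handle.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path,
    adapter_seq: str,
    min_overlap: int = 12,
    max_error_rate: float = 0.25,
) -> TrimReport:
    """Trim a whole FASTQ file, writing trimmed reads and a report."""
    report = TrimReport()
    with _open_maybe_gzip(out_path, "wt") as out:
        for read_id, seq, qual in iter_fastq(in_path):
            report.reads_in += 1
            trimmed = trim_adapter(TrimmedRead(read_id, seq), adapter_seq, min_overlap, max_error_rate)
            if trimmed is None:
                report.reads_discarded_empty += 1
                continue
            if trimmed.length < len(seq):
                report.reads_trimmed += 1
            out.write(f"@{read_id}\n{trimmed.sequence}\n+\n{qual[: trimmed.length]}\n")
    return report


def load_alignments(sam_path: str | Path) -> dict[str, AlignmentSet]:
    """Read SAM/BAM and keep each read's equal-best-score alignments.

    Scores come from the ``AS`` tag; if absent, ``-NM`` (negated mismatch
    count) is used as a fallback, with a single warning.  Per read,
    alignments scoring below the maximum are dropped and at most 50 are
    retained in deterministic (chrom, start) order.  Unaligned reads yield
    empty alignment sets.
    """
    warned_no_as = False
    per_read: dict[str, list[Alignment]] = {}
    sequences: dict[str, str] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            read_id = aln.query_name
            seq = aln.query_sequence
            if seq is not None and not aln.is_secondary and not aln.is_supplementary:
                sequences[read_id] = seq if not aln.is_reverse else seq  # stored as aligned
            per_read.setdefault(read_id, [])
            if aln.is_unmapped:
                continue
            if aln.has_tag("AS"):
                score = float(aln.get_tag("AS"))
            else:
                nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
                score = -float(nm)
                if not warned_no_as:
                    logger.warning("alignments missing AS tag; falling back to -NM as score")
                    warned_no_as = True
            nm = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
            strand = "-" if aln.is_reverse else "+"
            per_read[read_id].append(
                Alignment(
                    read_id,
                    GenomicInterval(aln.reference_name, aln.reference_start, aln.reference_end, strand),
                    score,
                    nm,
                )
            )

    out: dict[str, AlignmentSet] = {}
    for read_id, alns in per_read.items():
        seq = sequences.get(read_id)
        if seq is None:
            # secondary-only records with SEQ "*"; reconstruct length-only read
            length = len(alns[0].interval) if alns else 1
            seq = "N" * length
        best = max((a.score for a in alns), default=None)
        kept = sorted(
            (a for a in alns if a.score == best),
            key=lambda a: (a.interval.chrom, a.interval.start, a.interval.strand),
        )
        if len(kept) > MAX_ALIGNMENTS:
            logger.info("read %s: %d equal-best alignments, keeping first %d",
                        read_id, len(kept), MAX_ALIGNMENTS)
            kept = kept[:MAX_ALIGNMENTS]
        out[read_id] = AlignmentSet(TrimmedRead(read_id, seq), kept)
    return out
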