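"""Ungapped antisense search of tRNA fragments against mRNA 3' UTRs.

A fragment that silences a target in a miRNA/siRNA-like fashion should be
reverse-complementary to a stretch of the target's 3' UTR.  The search
reproduces an ungapped, complementary-strand-only nucleotide search:

* exact 6-mer reverse-complement seeds,
* ungapped extension with +1/-3 match/mismatch scoring, trimmed at both
  ends to the maximal raw score S,
* Karlin-Altschul statistics (bits = (lambda*S - ln K) / ln 2;
  E = K * space * exp(-lambda*S)) with the ungapped lambda = 1.374,
  K = 0.711 of the +1/-3 scoring system,
* a fixed effective search space: the length of the genomic union of all
  3' UTRs in the database, so overlapping UTR isoforms from the same
  locus are not double-counted,
* hits kept at E <= 1.0.

Each hit's genomic footprint is scored for evolutionary conservation
(mean of a per-base phyloP-like track) both absolutely and relative to
the shortest 3' UTR overlapping the hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_io import GenomicInterval, collapse_intervals, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KAParams:
    """Karlin-Altschul parameters of the ungapped +1/-3 scoring system."""

    lam: float = 1.374
    K: float = 0.711
    reward: int = 1
    penalty: int = -3

    def __post_init__(self) -> None:
        if self.lam <= 0 or not (0 < self.K < 1):
            raise ValueError("invalid Karlin-Altschul parameters")


@dataclass
class UTRRecord:
    transcript_id: str
    gene_name: str
    sequence: str
    genomic_intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        total = sum(len(iv) for iv in self.genomic_intervals)
        if total != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"interval span {total}"
            )

    def offsets_to_genomic(self, start: int, end: int) -> list[GenomicInterval]:
        """Map a sequence slice [start, end) to genomic intervals.

        Intervals are stored in genomic order; on the minus strand the
        sequence runs from the last interval's end backwards.
        """
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError("slice outside UTR sequence")
        strand = self.genomic_intervals[0].strand
        pieces: list[GenomicInterval] = []
        offset = 0
        ivs = (
            self.genomic_intervals
            if strand == "+"
            else list(reversed(self.genomic_intervals))
        )
        for iv in ivs:
            ln = len(iv)
            lo = max(start - offset, 0)
            hi = min(end - offset, ln)
            if hi > lo:
                if strand == "+":
                    pieces.append(
                        GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi, strand)
                    )
                else:
                    pieces.append(
                        GenomicInterval(iv.chrom, iv.end - hi, iv.end - lo, strand)
                    )
            offset += ln
        return pieces


@dataclass
class UTRDatabase:
    records: list[UTRRecord]
    effective_search_space: int

    def __iter__(self):
        return iter(self.records)


def build_utr_db(transcripts: Iterable[UTRRecord]) -> UTRDatabase:
    """Index UTR records; the search space is their genomic union length.

    Overlapping or duplicated UTR loci (isoforms of one gene) therefore
    count once.
    """
    records = list(transcripts)
    all_intervals = [iv for rec in records for iv in rec.genomic_intervals]
    merged = collapse_intervals(
        [GenomicInterval(iv.chrom, iv.start, iv.end, "+") for iv in all_intervals]
    )
    space = sum(len(iv) for iv in merged)
    return UTRDatabase(records, space)


def bitscore(raw_score: float, ka: KAParams = KAParams()) -> float:
    """Bit score of a raw ungapped score: (lambda*S - ln K) / ln 2."""
    return (ka.lam * raw_score - math.log(ka.K)) / math.log(2.0)


def evalue(raw_score: float, effective_search_space: float, ka: KAParams = KAParams()) -> float:
    """Expected chance hits at score >= S: K * space * exp(-lambda*S)."""
    if effective_search_space <= 0:
        raise ValueError("search space must be positive")
    return ka.K * effective_search_space * math.exp(-ka.lam * raw_score)


@dataclass
class ComplementarityHit:
    query_id: str
    transcript_id: str
    gene_name: str
    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    matches: int
    mismatches: int
    raw_score: int
    bit_score: float
    e_value: float
    conservation_value: float | None = None
    normalized_conservation: float | None = None
    genomic_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def hit_length(self) -> int:
        return self.matches + self.mismatches


def _search_one_subject(
    query_id: str,
    query: str,
    rec: UTRRecord,
    seed_len: int,
    ka: KAParams,
) -> list[tuple[int, int, int, int, int]]:
    """Seeded ungapped hits of revcomp(query) in one subject.

    Returns tuples (subject_start, subject_end, query_start, query_end,
    raw_score), deduplicated by subject interval.  The extension around
    each seed is trimmed at both ends to the maximal score: with additive
    scoring the best segment containing the seed is the seed plus the
    best-scoring left and right extensions.
    """
    rq = reverse_complement(query).upper()
    subject = rec.sequence.upper()
    qn, sn = len(rq), len(subject)
    if qn < seed_len:
        return []

    seeds: dict[int, list[int]] = {}  # seed start in rq -> subject starts
    kmer_pos: dict[str, list[int]] = {}
    for i in range(sn - seed_len + 1):
        kmer = subject[i : i + seed_len]
        if "N" in kmer:
            continue
        kmer_pos.setdefault(kmer, []).append(i)
    for j in range(qn - seed_len + 1):
        kmer = rq[j : j + seed_len]
        if "N" in kmer:
            continue
        if kmer in kmer_pos:
            seeds[j] = kmer_pos[kmer]

    def base_score(a: str, b: str) -> int:
        if a == "N" or b == "N" or a != b:
            return ka.penalty
        return ka.reward

    hits: dict[tuple[int, int], tuple[int, int, int, int, int]] = {}
    for j, subject_starts in seeds.items():
        for i in subject_starts:
            # best right extension: max prefix-sum to the right of the seed
            best_right_len, best_right_score = 0, 0
            acc = 0
            k = 0
            while j + seed_len + k < qn and i + seed_len + k < sn:
                acc += base_score(rq[j + seed_len + k], subject[i + seed_len + k])
                k += 1
                if acc > best_right_score:
                    best_right_score, best_right_len = acc, k
            # best left extension: max suffix-sum to the left of the seed
            best_left_len, best_left_score = 0, 0
            acc = 0
            k = 0
            while j - 1 - k >= 0 and i - 1 - k >= 0:
                acc += base_score(rq[j - 1 - k], subject[i - 1 - k])
                k += 1
                if acc > best_left_score:
                    best_left_score, best_left_len = acc, k
            q_lo = j - best_left_len
            q_hi = j + seed_len + best_right_len
            s_lo = i - best_left_len
            s_hi = i + seed_len + best_right_len
            raw = seed_len * ka.reward + best_left_score + best_right_score
            key = (s_lo, s_hi)
            prev = hits.get(key)
            if prev is None or raw > prev[4]:
                hits[key] = (s_lo, s_hi, q_lo, q_hi, raw)
    return sorted(hits.values())


def antisense_search(
    query_id: str,
    query: str,
    db: UTRDatabase,
    seed_len: int = 6,
    max_evalue: float = 1.0,
    ka: KAParams = KAParams(),
) -> list[ComplementarityHit]:
    """All seeded ungapped antisense hits of one query against the UTR db.

    The query is the fragment sequence 5'->3'; a hit means the fragment is
    reverse-complementary to the matched subject stretch.  Hits are
    filtered to ``e_value <= max_evalue`` and reported in deterministic
    (transcript, subject offset) order.
    """
    query = query.upper()
    frac_n = query.count("N") / max(len(query), 1)
    if frac_n > 0.2:
        raise ValueError(f"query {query_id}: too many ambiguous bases")
    results: list[ComplementarityHit] = []
    for rec in db.records:
        for s_lo, s_hi, q_lo, q_hi, raw in _search_one_subject(
            query_id, query, rec, seed_len, ka
        ):
            rq = reverse_complement(query).upper()
            segment_q = rq[q_lo:q_hi]
            segment_s = rec.sequence.upper()[s_lo:s_hi]
            matches = sum(a == b and a != "N" for a, b in zip(segment_q, segment_s))
            mismatches = len(segment_q) - matches
            e_val = evalue(raw, db.effective_search_space, ka)
            if e_val > max_evalue:
                continue
            # query coordinates in the original (5'->3') orientation
            n = len(query)
            results.append(
                ComplementarityHit(
                    query_id=query_id,
                    transcript_id=rec.transcript_id,
                    gene_name=rec.gene_name,
                    subject_start=s_lo,
                    subject_end=s_hi,
                    query_start=n - q_hi,
                    query_end=n - q_lo,
                    matches=matches,
                    mismatches=mismatches,
                    raw_score=raw,
                    bit_score=bitscore(raw, ka),
                    e_value=e_val,
                    genomic_intervals=rec.offsets_to_genomic(s_lo, s_hi),
                )
            )
    results.sort(key=lambda h: (h.transcript_id, h.subject_start, h.subject_end))
    return results


# ---------------------------------------------------------------------------
# Conservation


class ConservationTrack:
    """Per-base conservation values (phyloP-like), loadable from bedGraph."""

    def __init__(self, values: Mapping[str, Mapping[int, float]]):
        self._values = {chrom: dict(pos) for chrom, pos in values.items()}

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ConservationTrack":
        values: dict[str, dict[int, float]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split("\t")
                chrom_vals = values.setdefault(chrom, {})
                for pos in range(int(start), int(end)):
                    chrom_vals[pos] = float(value)
        return cls(values)

    def mean(self, intervals: Sequence[GenomicInterval]) -> float | None:
        """Arithmetic mean of per-base values over the intervals; None if uncovered."""
        vals: list[float] = []
        missing = 0
        for iv in intervals:
            chrom_vals = self._values.get(iv.chrom, {})
            for pos in range(iv.start, iv.end):
                if pos in chrom_vals:
                    vals.append(chrom_vals[pos])
                else:
                    missing += 1
        if not vals:
            return None
        if missing:
            logger.warning("conservation track missing %d of %d bases",
                           missing, missing + len(vals))
        return float(np.mean(vals))


def conservation_scores(
    hit: ComplementarityHit,
    track: ConservationTrack,
    db: UTRDatabase,
    mode: str = "ratio",
) -> tuple[float | None, float | None]:
    """Mean conservation over the hit and its value relative to the
    shortest overlapping 3' UTR.

    ``mode="ratio"`` divides the hit mean by the UTR mean; ``"difference"``
    reports hit mean - UTR mean + 1.  Both ways, values near 1 mean the
    matched site is conserved like its surrounding UTR.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    hit_mean = track.mean(hit.genomic_intervals)
    if hit_mean is None:
        logger.warning("no conservation data over hit %s:%s", hit.query_id, hit.transcript_id)
        return None, None

    overlapping = [
        rec
        for rec in db.records
        if any(
            hiv.chrom == riv.chrom and hiv.start < riv.end and riv.start < hiv.end
            for hiv in hit.genomic_intervals
            for riv in rec.genomic_intervals
        )
    ]
    if not overlapping:
        return hit_mean, None
    shortest = min(overlapping, key=lambda r: (len(r.sequence), r.transcript_id))
    utr_mean = track.mean(shortest.genomic_intervals)
    if utr_mean is None or (mode == "ratio" and utr_mean == 0):
        return hit_mean, None
    if mode == "ratio":
        return hit_mean, hit_mean / utr_mean
    return hit_mean, hit_mean - utr_mean + 1.0


def annotate_conservation(
    hits: Sequence[ComplementarityHit],
    track: ConservationTrack,
    db: UTRDatabase,
    mode: str = "ratio",
) -> None:
    """Fill each hit's conservation fields in place."""
    for hit in hits:
        cons, norm = conservation_scores(hit, track, db, mode)
        hit.conservation_value = cons
        hit.normalized_conservation = norm


# ---------------------------------------------------------------------------
# IO helpers


def read_utr_fasta_bed(fasta_path: str | Path, bed_path: str | Path) -> list[UTRRecord]:
    """Load UTR sequences (FASTA, ids = transcript ids; description may hold
    the gene name) and their genomic intervals (BED6, name = transcript id)."""
    from Bio import SeqIO

    intervals: dict[str, list[GenomicInterval]] = {}
    with open(bed_path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            intervals.setdefault(name, []).append(
                GenomicInterval(chrom, int(start), int(end), strand)
            )
    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = seq_rec.description.split()
        gene_name = parts[1] if len(parts) > 1 else seq_rec.id
        if seq_rec.id not in intervals:
            raise ValueError(f"UTR {seq_rec.id} missing from BED")
        records.append(
            UTRRecord(
                transcript_id=seq_rec.id,
                gene_name=gene_name,
                sequence=str(seq_rec.seq),
                genomic_intervals=sorted(intervals[seq_rec.id]),
            )
        )
    return records


def write_hits_tsv(hits: Sequence[ComplementarityHit], queries: Mapping[str, str], path) -> None:
    """Hits table: query, query sequence, hit length, e value, bitscore,
    gene name, conservation value, normalized conservation value."""
    with open(path, "w") as out:
        out.write(
            "query\tquery_sequence\thit_length\te_value\tbit_score\tgene_name\t"
            "conservation_value\tnormalized_conservation\n"
        )
        for h in hits:
            cons = "" if h.conservation_value is None else f"{h.conservation_value:.3f}"
            norm = "" if h.normalized_conservation is None else f"{h.normalized_conservation:.3f}"
            out.write(
                f"{h.query_id}\t{queries.get(h.query_id, '')}\t{h.hit_length}\t"
                f"{h.e_value:.3g}\t{h.bit_score:.1f}\t{h.gene_name}\t{cons}\t{norm}\n"
            )
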