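"""Descriptive outputs: count tables, class fractions, rpm, length
distributions, per-gene coverage and top-k abundance shares."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationRecord
from .feature_assignment import AMBIGUOUS, UNANNOTATED, FeatureCall, reporting_class
from .read_processing import Alignment

LENGTH_RANGE = (15, 90)  # nt span of the sequenced library inserts


def calls_to_frame(calls_by_sample: Mapping[str, Sequence[FeatureCall]]) -> pd.DataFrame:
    """Long DataFrame over all samples' calls (sample, read_id, length, class, refined)."""
    rows = []
    for sample, calls in calls_by_sample.items():
        for call in calls:
            rows.append(
                (sample, call.read_id, call.read_length,
                 reporting_class(call.featuretype), call.refined_label or "")
            )
    return pd.DataFrame(rows, columns=["sample", "read_id", "length", "rna_class", "refined_label"])


def class_fractions(
    calls_by_sample: Mapping[str, Sequence[FeatureCall]],
    include_unannotated: bool = False,
) -> pd.DataFrame:
    """Per-sample RNA-class proportions (classes x samples).

    "Ambiguous" is an included class; "Unannotated" is excluded from the
    denominator unless requested.  Each column sums to 1.
    """
    frame = calls_to_frame(calls_by_sample)
    if not include_unannotated:
        frame = frame[frame.rna_class != UNANNOTATED]
    if frame.empty or (frame.groupby("sample").size() == 0).any():
        raise ValueError("no assigned reads for at least one sample")
    counts = frame.pivot_table(
        index="rna_class", columns="sample", values="read_id", aggfunc="count", fill_value=0
    )
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with zero assigned reads")
    return counts / counts.sum(axis=0)


def class_counts(
    calls_by_sample: Mapping[str, Sequence[FeatureCall]],
    include_special: bool = False,
) -> pd.DataFrame:
    """RNA-class x sample read-count matrix (resolved classes only by default)."""
    frame = calls_to_frame(calls_by_sample)
    if not include_special:
        frame = frame[~frame.rna_class.isin([AMBIGUOUS, UNANNOTATED])]
    return frame.pivot_table(
        index="rna_class", columns="sample", values="read_id", aggfunc="count", fill_value=0
    ).astype(int)


def refined_counts(
    calls_by_sample: Mapping[str, Sequence[FeatureCall]],
    rna_class: str | None = None,
) -> pd.DataFrame:
    """Refined-feature x sample read counts, optionally for one RNA class."""
    frame = calls_to_frame(calls_by_sample)
    frame = frame[~frame.rna_class.isin([AMBIGUOUS, UNANNOTATED])]
    if rna_class is not None:
        frame = frame[frame.rna_class == rna_class]
    return frame.pivot_table(
        index="refined_label", columns="sample", values="read_id", aggfunc="count", fill_value=0
    ).astype(int)


def unique_sequence_counts(
    sequences_by_sample: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Unique-sequence x sample counts (identical trimmed sequences collapsed)."""
    frames = {
        sample: pd.Series(list(seqs)).value_counts()
        for sample, seqs in sequences_by_sample.items()
    }
    return pd.DataFrame(frames).fillna(0).astype(int).rename_axis("sequence")


def rpm_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to reads-per-million (columns sum to 1e6)."""
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot rpm-normalize a zero-sum sample column")
    return matrix / totals * 1e6


def length_distribution(
    calls_by_sample: Mapping[str, Sequence[FeatureCall]],
    by_featuretype: bool = True,
    length_range: tuple[int, int] = LENGTH_RANGE,
) -> pd.DataFrame:
    """Read-length histograms per sample (and per RNA class).

    Long format: sample, rna_class ("all" when not split), length, count.
    Lengths outside ``length_range`` are clipped into the terminal bins so
    every read is counted.
    """
    lo, hi = length_range
    frame = calls_to_frame(calls_by_sample)
    frame = frame.assign(length=frame.length.clip(lo, hi))
    group_cols = ["sample", "rna_class", "length"] if by_featuretype else ["sample", "length"]
    hist = frame.groupby(group_cols).size().rename("count").reset_index()
    if not by_featuretype:
        hist.insert(1, "rna_class", "all")
    return hist


def gene_coverage(
    alignments_with_support: Sequence[tuple[Alignment, int]],
    gene: AnnotationRecord,
    library_size: int | None = None,
) -> np.ndarray:
    """Per-base read depth over a gene body, 5'->3' in gene orientation.

    ``alignments_with_support`` pairs each alignment with the number of
    genes its read's call supports; the alignment contributes 1/n depth to
    each, so total signal is conserved across co-supported genes.  With
    ``library_size`` the profile is rpm-scaled.
    """
    glen = gene.end - gene.start
    profile = np.zeros(glen, dtype=float)
    for aln, n_support in alignments_with_support:
        iv = aln.interval
        if iv.chrom != gene.chrom:
            continue
        lo = max(iv.start, gene.start) - gene.start
        hi = min(iv.end, gene.end) - gene.start
        if hi > lo:
            profile[lo:hi] += 1.0 / max(n_support, 1)
    if gene.strand == "-":
        profile = profile[::-1]
    if library_size:
        profile = profile / library_size * 1e6
    return profile


def top_k_fraction(rpm_column: pd.Series, k: int) -> float:
    """Percentage of a class's rpm pool captured by its k most abundant members.

    The column is an rpm vector over one class (summing to 1e6).  Ties at
    the cut are broken by label order for determinism.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return 0.0
    ordered = rpm_column.sort_index().sort_values(ascending=False, kind="stable")
    return float(ordered.iloc[:k].sum() / 1e6 * 100)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def write_coverage_bedgraph(
    profile: np.ndarray, gene: AnnotationRecord, path: str | Path
) -> None:
    """Write a coverage profile as bedGraph in genomic orientation."""
    values = profile[::-1] if gene.strand == "-" else profile
    with open(path, "w") as out:
        for offset, value in enumerate(values):
            if value != 0:
                pos = gene.start + offset
                out.write(f"{gene.chrom}\t{pos}\t{pos + 1}\t{value:.6g}\n")
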