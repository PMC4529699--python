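"""End-to-end orchestration: annotations -> assignment -> quantification ->
statistics -> tRNA fragments -> antisense search, with TSV outputs and a
run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from importlib.metadata import version as _dist_version

from . import (
    annotation_io,
    complementarity,
    feature_assignment,
    quantification,
    read_processing,
    stats,
    trna_fragments,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full run.

    ``samples`` maps sample name -> SAM path; ``groups`` maps sample name
    -> "cell" | "exosome".
    """

    samples: Mapping[str, str | Path]
    groups: Mapping[str, str]
    gencode_gtf: str | Path
    mirbase_gff: str | Path
    trna_bed: str | Path
    trna_metadata: str | Path
    pirna_bed: str | Path
    repeats_tsv: str | Path
    outdir: str | Path
    utr_fasta: str | Path | None = None
    utr_bed: str | Path | None = None
    conservation_bedgraph: str | Path | None = None
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    stranded: bool = True
    include_unannotated: bool = False
    prior_count: float = 0.125
    top_n_fragments: int = 20
    seed: int = 0
    conservation_mode: str = "ratio"

    def validate(self) -> None:
        for label, path in [
            ("gencode_gtf", self.gencode_gtf),
            ("mirbase_gff", self.mirbase_gff),
            ("trna_bed", self.trna_bed),
            ("trna_metadata", self.trna_metadata),
            ("pirna_bed", self.pirna_bed),
            ("repeats_tsv", self.repeats_tsv),
            *[(f"sam:{name}", p) for name, p in self.samples.items()],
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: missing input file {path}")


@dataclass
class ResultBundle:
    calls_by_sample: dict
    alignment_sets_by_sample: dict
    class_fractions: pd.DataFrame
    class_counts: pd.DataFrame
    length_hist: pd.DataFrame
    differential_classes: pd.DataFrame | None
    mirna_rpm: pd.DataFrame | None
    fragment_calls_by_sample: dict
    anticodon_profile: pd.DataFrame
    top_fragment_sequences: list[str]
    hits: list
    outdir: Path
    manifest: dict = field(default_factory=dict)


def _md5(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_annotation_index(config: PipelineConfig) -> annotation_io.FeatureIndex:
    records = (
        annotation_io.load_gencode(config.gencode_gtf)
        + annotation_io.load_mirbase(config.mirbase_gff)
        + annotation_io.load_trna(config.trna_bed, config.trna_metadata)
        + annotation_io.load_pirna(config.pirna_bed)
        + annotation_io.load_repeats(config.repeats_tsv)
    )
    return annotation_io.build_index(records)


def _trna_fragment_calls(
    calls, alignment_sets, index: annotation_io.FeatureIndex
) -> list[trna_fragments.FragmentCall]:
    by_id = {rec.record_id: rec for rec in index.records}
    out = []
    for call in calls:
        if call.featuretype != "tRNA" or not call.supporting_records:
            continue
        gene = by_id[call.supporting_records[0]]
        aset = alignment_sets[call.read_id]
        aln = next(
            (a for a in aset.alignments if a.interval.overlaps(gene.intervals[0], stranded=False)),
            None,
        )
        if aln is not None:
            out.append(trna_fragments.classify_fragment(aln, gene))
    return out


def run_all(config: PipelineConfig) -> ResultBundle:
    """Execute every stage on the configured inputs and write the outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    index = load_annotation_index(config)
    annotation_io.write_annotation_tsv(index.records, outdir / "annotations.tsv")

    calls_by_sample = {}
    asets_by_sample = {}
    for sample, sam_path in sorted(config.samples.items()):
        asets = read_processing.load_alignments(sam_path)
        calls = feature_assignment.assign_all(asets, index, stranded=config.stranded)
        calls_by_sample[sample] = calls
        asets_by_sample[sample] = asets
        feature_assignment.write_calls_tsv(calls, outdir / f"{sample}.calls.tsv")

    fractions = quantification.class_fractions(
        calls_by_sample, include_unannotated=config.include_unannotated
    )
    quantification.write_matrix_tsv(fractions, outdir / "class_fractions.tsv", "rna_class")
    counts = quantification.class_counts(calls_by_sample)
    quantification.write_matrix_tsv(counts, outdir / "class_counts.tsv", "rna_class")
    hist = quantification.length_distribution(calls_by_sample)
    hist.to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)

    # class-level differential representation (total library sizes as
    # normalization; TMM is reserved for refined features)
    differential = None
    if len(set(config.groups.values())) == 2:
        phi = stats.estimate_common_dispersion(counts, config.groups)
        differential = stats.exact_test_nb(
            counts, config.groups, phi, prior_count=config.prior_count,
            reference_group="cell" if "cell" in config.groups.values() else None,
        ).sort_values("logFC", ascending=False)
        differential.to_csv(outdir / "differential_classes.tsv", sep="\t")

    mirna_counts = quantification.refined_counts(calls_by_sample, rna_class="miRNA_processed")
    mirna_rpm = None
    if not mirna_counts.empty:
        mirna_rpm = quantification.rpm_normalize(mirna_counts)
        quantification.write_matrix_tsv(mirna_rpm, outdir / "mirna_rpm.tsv", "miRNA")

    fragment_calls = {
        sample: _trna_fragment_calls(calls, asets_by_sample[sample], index)
        for sample, calls in calls_by_sample.items()
    }
    for sample, fcalls in fragment_calls.items():
        trna_fragments.write_fragment_tsv(fcalls, outdir / f"{sample}.trna_fragments.tsv")
    profile = trna_fragments.anticodon_profile(fragment_calls)
    quantification.write_matrix_tsv(profile, outdir / "anticodon_profile.tsv", "anticodon")

    # top tRNA fragment sequences feed the antisense search
    seq_counts = {}
    for sample, calls in calls_by_sample.items():
        trna_ids = {c.read_id for c in calls if c.featuretype == "tRNA"}
        counter: dict[str, int] = {}
        for read_id in trna_ids:
            seq = asets_by_sample[sample][read_id].read.sequence
            counter[seq] = counter.get(seq, 0) + 1
        seq_counts[sample] = counter
    top_seqs = trna_fragments.top_fragments(seq_counts, n=config.top_n_fragments)
    trna_fragments.write_fasta(top_seqs, outdir / "top_trna_fragments.fa")

    hits: list = []
    if config.utr_fasta and config.utr_bed:
        utrs = complementarity.read_utr_fasta_bed(config.utr_fasta, config.utr_bed)
        db = complementarity.build_utr_db(utrs)
        queries = {f"frag{i + 1}": seq for i, seq in enumerate(top_seqs)}
        for qid, seq in queries.items():
            hits.extend(complementarity.antisense_search(qid, seq, db))
        if config.conservation_bedgraph:
            track = complementarity.ConservationTrack.from_bedgraph(config.conservation_bedgraph)
            complementarity.annotate_conservation(hits, track, db, mode=config.conservation_mode)
        complementarity.write_hits_tsv(hits, queries, outdir / "complementarity_hits.tsv")

    manifest = {
        "version": _dist_version("exosmallrna"),
        "parameters": {
            "adapter": config.adapter,
            "stranded": config.stranded,
            "include_unannotated": config.include_unannotated,
            "prior_count": config.prior_count,
            "top_n_fragments": config.top_n_fragments,
            "seed": config.seed,
            "conservation_mode": config.conservation_mode,
        },
        "inputs": {
            str(name): _md5(path)
            for name, path in [
                ("gencode_gtf", config.gencode_gtf),
                ("mirbase_gff", config.mirbase_gff),
                ("trna_bed", config.trna_bed),
                ("pirna_bed", config.pirna_bed),
                ("repeats_tsv", config.repeats_tsv),
                *[(s, p) for s, p in sorted(config.samples.items())],
            ]
        },
        "samples": {s: len(c) for s, c in calls_by_sample.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ResultBundle(
        calls_by_sample=calls_by_sample,
        alignment_sets_by_sample=asets_by_sample,
        class_fractions=fractions,
        class_counts=counts,
        length_hist=hist,
        differential_classes=differential,
        mirna_rpm=mirna_rpm,
        fragment_calls_by_sample=fragment_calls,
        anticodon_profile=profile,
        top_fragment_sequences=top_seqs,
        hits=hits,
        outdir=outdir,
    )


def report(bundle: ResultBundle) -> dict[str, Path]:
    """Summary tables: per-sample top-20 miRNAs by rpm and classes by logFC."""
    outdir = bundle.outdir
    paths = {}
    if bundle.mirna_rpm is not None:
        rows = []
        for sample in bundle.mirna_rpm.columns:
            col = bundle.mirna_rpm[sample].sort_index().sort_values(ascending=False, kind="stable")
            for rank, (mirna, rpm) in enumerate(col.iloc[:20].items(), start=1):
                rows.append((sample, rank, mirna, round(float(rpm), 1)))
        top_mirna = pd.DataFrame(rows, columns=["sample", "rank", "miRNA", "rpm"])
        paths["top_mirna"] = outdir / "report_top_mirna.tsv"
        top_mirna.to_csv(paths["top_mirna"], sep="\t", index=False)
    if bundle.differential_classes is not None:
        paths["classes_by_logfc"] = outdir / "report_classes_by_logfc.tsv"
        bundle.differential_classes.to_csv(paths["classes_by_logfc"], sep="\t")
    return paths
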