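"""Self-contained synthetic small-RNA dataset generator.

Builds a toy genome (~100 kb plus a UTR contig), the five annotation
sources, per-sample reads (FASTQ with adapter, ground-truth SAM with all
equal-score placements for multi-mappers) and a conservation track, with
a truth table for every read.  The defaults emulate the study design the
pipeline targets: a two-condition (cell vs exosome), two-tissue
(ASC vs BMSC) layout in which

* cell libraries are dominated by ~22-nt mature miRNAs and snoRNAs with
  mostly full-length tRNAs,
* exosome libraries carry a four-fold enriched tRNA class dominated by
  ~33-nt 5' halves (other classes untouched apart from compositional
  rescaling),
* repeat-derived reads multi-map across byte-identical repeat copies,
* deliberate annotation overlaps (a miRNA inside a repeat, a snoRNA
  overlapping a repeat) exercise the disambiguation cascade.

All randomness flows from one seeded generator, so a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import (
    AnnotationRecord,
    GenomicInterval,
    anticodon_to_aa,
    reverse_complement,
)
from .read_processing import Alignment

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

#: default RNA-class mixture of a cell library (fractions sum to 1;
#: "unannotated" reads come from a bare genomic region)
CELL_MIXTURE = {
    "miRNA_processed": 0.30,
    "snoRNA": 0.26,
    "tRNA": 0.06,
    "repeat": 0.10,
    "rRNA": 0.06,
    "miscRNA": 0.05,
    "snRNA": 0.05,
    "piRNA": 0.08,
    "unannotated": 0.04,
}

#: fold-change of the tRNA class fraction in exosomes versus cells
TRNA_EXOSOME_FOLD = 4.0

#: tRNA fragment composition per condition (shares within the tRNA class)
FRAGMENT_COMPOSITION = {
    "cell": {"five_prime_half": 0.20, "full_length": 0.70, "other": 0.10},
    "exosome": {"five_prime_half": 0.70, "full_length": 0.30, "other": 0.0},
}

#: per-(tissue, condition) anticodon weights; Glu-CTC dominates cells,
#: ASC exosomes switch to Gly-GCC
TRNA_WEIGHTS = {
    ("ASC", "cell"): {"CTC": 0.60, "GCC": 0.05},
    ("BMSC_I", "cell"): {"CTC": 0.60, "GCC": 0.05},
    ("BMSC_II", "cell"): {"CTC": 0.60, "GCC": 0.05},
    ("ASC", "exosome"): {"GCC": 0.60, "CTC": 0.15},
    ("BMSC_I", "exosome"): {"CTC": 0.65, "GCC": 0.10},
    ("BMSC_II", "exosome"): {"CTC": 0.65, "GCC": 0.10},
}

DEFAULT_SAMPLES = (
    ("ASC1_cell", "cell", "ASC"),
    ("ASC2_cell", "cell", "ASC"),
    ("BMSC1_cell", "cell", "BMSC_I"),
    ("ASC1_exo", "exosome", "ASC"),
    ("ASC2_exo", "exosome", "ASC"),
    ("BMSC1_exo", "exosome", "BMSC_I"),
)


def exosome_mixture(cell_mixture: Mapping[str, float], trna_fold: float) -> dict[str, float]:
    """Exosome class mixture: tRNA fraction scaled by ``trna_fold`` among
    annotated classes, the rest rescaled to keep the total at 1."""
    unann = cell_mixture.get("unannotated", 0.0)
    annotated = {k: v for k, v in cell_mixture.items() if k != "unannotated"}
    total = sum(annotated.values())
    fracs = {k: v / total for k, v in annotated.items()}
    new_trna = fracs["tRNA"] * trna_fold
    if new_trna >= 1:
        raise ValueError("tRNA fold too large for the mixture")
    scale = (1 - new_trna) / (1 - fracs["tRNA"])
    out = {k: (new_trna if k == "tRNA" else v * scale) for k, v in fracs.items()}
    out = {k: v * (1 - unann) for k, v in out.items()}
    out["unannotated"] = unann
    return out


@dataclass
class SimulationConfig:
    seed: int = 42
    samples: Sequence[tuple[str, str, str]] = DEFAULT_SAMPLES
    n_reads: int = 50_000
    cell_mixture: Mapping[str, float] = field(default_factory=lambda: dict(CELL_MIXTURE))
    trna_fold: float = TRNA_EXOSOME_FOLD
    fragment_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in FRAGMENT_COMPOSITION.items()}
    )
    adapter: str = DEFAULT_ADAPTER

    def mixture_for(self, condition: str) -> dict[str, float]:
        if condition == "cell":
            return dict(self.cell_mixture)
        return exosome_mixture(self.cell_mixture, self.trna_fold)


# ---------------------------------------------------------------------------
# Toy genome


@dataclass
class ToyGenome:
    """Genome sequences plus every annotation, in memory and writable."""

    sequences: dict[str, str]
    gencode: list[AnnotationRecord]
    mirbase: list[AnnotationRecord]
    trna: list[AnnotationRecord]
    pirna_raw: list[GenomicInterval]  # pre-collapse member intervals
    pirna: list[AnnotationRecord]
    repeats: list[AnnotationRecord]
    utrs: list  # list[complementarity.UTRRecord]; deferred import
    planted_sites: list[dict]

    def all_records(self) -> list[AnnotationRecord]:
        return self.gencode + self.mirbase + self.trna + self.pirna + self.repeats

    def fetch(self, iv: GenomicInterval) -> str:
        """Insert sequence of an interval, 5'->3' of the annotated strand."""
        seq = self.sequences[iv.chrom][iv.start : iv.end]
        return reverse_complement(seq) if iv.strand == "-" else seq

    # -- file output -------------------------------------------------------

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gencode": outdir / "gencode_small.gtf",
            "mirbase": outdir / "mirbase.gff3",
            "trna_bed": outdir / "trna.bed",
            "trna_meta": outdir / "trna_metadata.tsv",
            "pirna": outdir / "pirna.bed",
            "repeats": outdir / "repeats.tsv",
            "utr_fasta": outdir / "utrs.fa",
            "utr_bed": outdir / "utrs.bed",
        }
        with open(paths["genome"], "w") as out:
            for chrom in sorted(self.sequences):
                out.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    out.write(seq[i : i + 60] + "\n")
        with open(paths["gencode"], "w") as out:
            for rec in self.gencode:
                gene_type = rec.metadata["gene_type"]
                for kind in ("transcript", "exon"):
                    for iv in rec.intervals:
                        attrs = (
                            f'gene_id "{rec.record_id}"; transcript_id "{rec.record_id}.1"; '
                            f'gene_type "{gene_type}"; gene_name "{rec.name}";'
                        )
                        out.write(
                            f"{iv.chrom}\ttoy\t{kind}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                        )
        with open(paths["mirbase"], "w") as out:
            out.write("##gff-version 3\n")
            for rec in self.mirbase:
                iv = rec.intervals[0]
                if rec.featuretype == "miRNA_premature":
                    out.write(
                        f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{iv.strand}\t.\tID={rec.record_id};Name={rec.name}\n"
                    )
            for rec in self.mirbase:
                iv = rec.intervals[0]
                if rec.featuretype == "miRNA_processed":
                    parent = rec.metadata.get("parent", "")
                    out.write(
                        f"{iv.chrom}\t.\tmiRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                        f"ID={rec.record_id};Name={rec.name};Derives_from={parent}\n"
                    )
        with open(paths["trna_bed"], "w") as out:
            for rec in self.trna:
                iv = rec.intervals[0]
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.record_id}\t0\t{iv.strand}\n")
        with open(paths["trna_meta"], "w") as out:
            out.write("#gene_id\tanticodon\taa\n")
            for rec in self.trna:
                out.write(f"{rec.record_id}\t{rec.metadata['anticodon']}\t{rec.metadata['aa']}\n")
        with open(paths["pirna"], "w") as out:
            for i, iv in enumerate(self.pirna_raw):
                out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpiR_{i + 1}\t0\t{iv.strand}\n")
        with open(paths["repeats"], "w") as out:
            out.write("#name\tfamily\tchrom\tstart\tend\tstrand\n")
            for rec in self.repeats:
                iv = rec.intervals[0]
                out.write(
                    f"{rec.name}\t{rec.metadata['family']}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n"
                )
        with open(paths["utr_fasta"], "w") as out:
            for utr in self.utrs:
                out.write(f">{utr.transcript_id} {utr.gene_name}\n{utr.sequence}\n")
        with open(paths["utr_bed"], "w") as out:
            for utr in self.utrs:
                for iv in utr.genomic_intervals:
                    out.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{utr.transcript_id}\t0\t{iv.strand}\n"
                    )
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_toy_genome(config: SimulationConfig | None = None, rng: np.random.Generator | None = None) -> ToyGenome:
    """Construct the toy genome and all annotation sources.

    Layout on chrT (100 kb): 10 miRNA precursors with 5p/3p arms, 8
    snoRNAs, 3 each of rRNA/miscRNA/snRNA, 6 tRNAs (anticodons including
    Glu-CTC and Gly-GCC), 2 piRNA clusters built from overlapping member
    intervals, and 2 repeat families with 3 byte-identical copies each.
    chrU carries eight 3' UTRs (two sharing a locus) with planted
    antisense sites for the tRNA 5' halves.
    """
    from .complementarity import UTRRecord  # local import to avoid a cycle

    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)

    chrT = list(_random_seq(rng, 100_000))
    gencode: list[AnnotationRecord] = []
    mirbase: list[AnnotationRecord] = []
    trna: list[AnnotationRecord] = []
    repeats: list[AnnotationRecord] = []

    # miRNA precursors with mature arms
    for i in range(10):
        start = 1000 + i * 300
        strand = "+" if i % 3 else "-"
        pre_id = f"toy-mir-{i + 1}"
        pre = AnnotationRecord(
            pre_id, pre_id, "miRNA_premature",
            [GenomicInterval("chrT", start, start + 80, strand)],
            {"mirna_name": pre_id},
        )
        mirbase.append(pre)
        # arms in gene orientation: 5p near the 5' end of the precursor
        if strand == "+":
            arm5 = GenomicInterval("chrT", start + 10, start + 32, strand)
            arm3 = GenomicInterval("chrT", start + 48, start + 70, strand)
        else:
            arm5 = GenomicInterval("chrT", start + 48, start + 70, strand)
            arm3 = GenomicInterval("chrT", start + 10, start + 32, strand)
        for arm, iv in (("5p", arm5), ("3p", arm3)):
            name = f"toy-miR-{i + 1}-{arm}"
            mirbase.append(
                AnnotationRecord(
                    name, name, "miRNA_processed", [iv],
                    {"mirna_name": name, "arm": arm, "parent": pre_id},
                )
            )

    def add_gencode(prefix: str, gene_type: str, n: int, length: int, base: int, step: int):
        for i in range(n):
            start = base + i * step
            strand = "+" if i % 2 == 0 else "-"
            gene_id = f"{prefix}{i + 1}"
            gencode.append(
                AnnotationRecord(
                    gene_id, gene_id, "gencode_small",
                    [GenomicInterval("chrT", start, start + length, strand)],
                    {"gene_type": gene_type},
                )
            )

    add_gencode("SNORD_T", "snoRNA", 8, 90, 5000, 300)
    add_gencode("RNA5S_T", "rRNA", 3, 110, 8000, 300)
    add_gencode("MISC_T", "miscRNA", 3, 100, 9500, 300)
    add_gencode("RNU_T", "snRNA", 3, 100, 10500, 300)

    anticodons = ["CTC", "GCC", "CAT", "TGC", "GTT", "AGA"]
    for i, anticodon in enumerate(anticodons):
        start = 12000 + i * 200
        strand = "+" if i < 4 else "-"
        gene_id = f"tRNA-{anticodon_to_aa(anticodon)}-{anticodon}-{i + 1}"
        trna.append(
            AnnotationRecord(
                gene_id, gene_id, "tRNA",
                [GenomicInterval("chrT", start, start + 72, strand)],
                {"anticodon": anticodon, "aa": anticodon_to_aa(anticodon)},
            )
        )

    pirna_raw = [
        GenomicInterval("chrT", 14000, 14120, "+"),
        GenomicInterval("chrT", 14100, 14220, "+"),
        GenomicInterval("chrT", 14200, 14300, "+"),
        GenomicInterval("chrT", 15000, 15110, "-"),
        GenomicInterval("chrT", 15100, 15200, "-"),
    ]
    pirna = [
        AnnotationRecord(
            "piRNA_cluster_1", "piRNA_cluster_1", "piRNA",
            [GenomicInterval("chrT", 14000, 14300, "+")], {},
        ),
        AnnotationRecord(
            "piRNA_cluster_2", "piRNA_cluster_2", "piRNA",
            [GenomicInterval("chrT", 15000, 15200, "-")], {},
        ),
    ]

    # repeat families: identical copies to force multi-mapping
    repeat_specs = [("AluT", "SINE/Alu", [20000, 21000, 22000]), ("L1T", "LINE/L1", [25000, 26000, 27000])]
    for name, family, starts in repeat_specs:
        consensus = _random_seq(rng, 300)
        for j, start in enumerate(starts):
            chrT[start : start + 300] = list(consensus)
            repeats.append(
                AnnotationRecord(
                    f"{name}_{j + 1}", name, "repeat",
                    [GenomicInterval("chrT", start, start + 300, "+")],
                    {"family": family},
                )
            )
    # planted overlaps: repeat annotations over miRNA precursor 1 and snoRNA 1
    repeats.append(
        AnnotationRecord(
            "AluT_mir", "AluT", "repeat",
            [GenomicInterval("chrT", 990, 1100, "-")], {"family": "SINE/Alu"},
        )
    )
    repeats.append(
        AnnotationRecord(
            "L1T_snord", "L1T", "repeat",
            [GenomicInterval("chrT", 4990, 5100, "+")], {"family": "LINE/L1"},
        )
    )

    genome = {"chrT": "".join(chrT)}

    # UTR contig with planted antisense sites for the Glu-CTC and Gly-GCC
    # tRNA 5' halves
    chrU = list(_random_seq(rng, 6000))
    glu_gene = trna[0]
    gly_gene = trna[1]
    glu_half = genome["chrT"][glu_gene.start : glu_gene.start + 33]
    if glu_gene.strand == "-":
        glu_half = reverse_complement(genome["chrT"][glu_gene.end - 33 : glu_gene.end])
    gly_half = genome["chrT"][gly_gene.start : gly_gene.start + 33]

    planted_sites: list[dict] = []

    def block_left_flank(pos: int, query: str, prefix_len: int) -> None:
        # Guarantee the planted site is the maximal-scoring extension: the
        # two subject bases left of the site are forced to mismatch the
        # continuation of the reverse-complemented query.
        rotate = {"A": "C", "C": "G", "G": "T", "T": "A"}
        rq = reverse_complement(query)
        idx0 = len(query) - prefix_len
        for k in (1, 2):
            if pos - k < 0 or idx0 - k < 0:
                break
            chrU[pos - k] = rotate[rq[idx0 - k]]

    # site 1: 20-nt antisense to the Glu-CTC half with one interior mismatch
    site1 = list(reverse_complement(glu_half[:20]))
    orig = site1[10]
    site1[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
    site1_seq = "".join(site1)
    pos1 = 300
    chrU[pos1 : pos1 + 20] = list(site1_seq)
    block_left_flank(pos1, glu_half, 20)
    planted_sites.append(
        {"chrom": "chrU", "start": pos1, "end": pos1 + 20, "query": glu_half,
         "matches": 19, "mismatches": 1, "raw_score": 16}
    )
    # site 2: perfect 14-nt antisense to the Gly-GCC half
    site2_seq = reverse_complement(gly_half[:14])
    pos2 = 1450
    chrU[pos2 : pos2 + 14] = list(site2_seq)
    block_left_flank(pos2, gly_half, 14)
    planted_sites.append(
        {"chrom": "chrU", "start": pos2, "end": pos2 + 14, "query": gly_half,
         "matches": 14, "mismatches": 0, "raw_score": 14}
    )
    genome["chrU"] = "".join(chrU)

    utr_specs = [
        ("UTR1.1", "TFCP2L1t", 200, 600),   # holds site 1
        ("UTR1.2", "TFCP2L1t", 250, 560),   # isoform sharing the locus
        ("UTR2.1", "GCM1t", 1400, 1700),    # holds site 2
        ("UTR3.1", "RUNX2t", 2000, 2350),
        ("UTR4.1", "SMAD3t", 2600, 2900),
        ("UTR5.1", "SOX11t", 3200, 3500),
        ("UTR6.1", "GOLGA6At", 3900, 4200),
        ("UTR7.1", "THAP5t", 4500, 4900),
    ]
    utrs = [
        UTRRecord(tid, gene, genome["chrU"][start:end],
                  [GenomicInterval("chrU", start, end, "+")])
        for tid, gene, start, end in utr_specs
    ]

    return ToyGenome(
        sequences=genome,
        gencode=gencode,
        mirbase=mirbase,
        trna=trna,
        pirna_raw=pirna_raw,
        pirna=pirna,
        repeats=repeats,
        utrs=utrs,
        planted_sites=planted_sites,
    )


# ---------------------------------------------------------------------------
# Read simulation


def _largest_remainder(weights: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` by ``weights`` (exact, no drift)."""
    keys = sorted(weights)
    raw = {k: weights[k] * total for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = total - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


@dataclass
class SimulatedRead:
    read_id: str
    sample: str
    rna_class: str
    gene_id: str
    fragment_class: str
    insert: str
    placements: list[GenomicInterval]


@dataclass
class SimulatedSample:
    name: str
    condition: str
    tissue: str
    reads: list[SimulatedRead]

    def alignment_sets(self):
        """In-memory AlignmentSet per read (equal-score ground truth)."""
        from .read_processing import AlignmentSet, TrimmedRead

        out = {}
        for read in self.reads:
            alns = [
                Alignment(read.read_id, iv, 0.0, 0)
                for iv in sorted(read.placements, key=lambda i: (i.chrom, i.start, i.strand))
            ]
            out[read.read_id] = AlignmentSet(TrimmedRead(read.read_id, read.insert), alns)
        return out


def _mirna_weights(tissue: str, n: int) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = 1.0 / ranks
    if tissue.startswith("BMSC"):
        w = w[::-1].copy()
    return w / w.sum()


def _trna_weights(tissue: str, condition: str, anticodons: Sequence[str]) -> np.ndarray:
    named = TRNA_WEIGHTS.get((tissue, condition), {"CTC": 0.6, "GCC": 0.05})
    rest = [a for a in anticodons if a not in named]
    remainder = 1.0 - sum(named.values())
    w = np.array([named.get(a, remainder / len(rest)) for a in anticodons])
    return w / w.sum()


def simulate_sample(
    config: SimulationConfig,
    toy: ToyGenome,
    name: str,
    condition: str,
    tissue: str,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Draw one sample's reads per the configured class mixture.

    Class totals follow the mixture exactly (largest-remainder
    apportionment); genes within a class are drawn multinomially.
    """
    mixture = config.mixture_for(condition)
    class_counts = _largest_remainder(mixture, config.n_reads)
    reads: list[SimulatedRead] = []
    idx = 0

    def new_id() -> str:
        nonlocal idx
        idx += 1
        return f"{name}_r{idx:06d}"

    chrT = toy.sequences["chrT"]

    def single(iv: GenomicInterval) -> list[GenomicInterval]:
        return [iv]

    # miRNA: mature arms, 22 +/- 1 nt
    mirna_mature = [r for r in toy.mirbase if r.featuretype == "miRNA_processed"]
    pre_by_parent = {r.record_id: r for r in toy.mirbase if r.featuretype == "miRNA_premature"}
    precursors = sorted(pre_by_parent)
    w_pre = _mirna_weights(tissue, len(precursors))
    for _ in range(class_counts.get("miRNA_processed", 0)):
        parent = precursors[rng.choice(len(precursors), p=w_pre)]
        arms = [r for r in mirna_mature if r.metadata.get("parent") == parent]
        arm = arms[rng.choice(len(arms), p=[0.7, 0.3])]
        iv0 = arm.intervals[0]
        delta = int(rng.integers(-1, 2))  # 21-23 nt, trimmed at the 3' end
        if iv0.strand == "+":
            iv = GenomicInterval(iv0.chrom, iv0.start, iv0.end + delta, iv0.strand)
        else:
            iv = GenomicInterval(iv0.chrom, iv0.start - delta, iv0.end, iv0.strand)
        reads.append(
            SimulatedRead(new_id(), name, "miRNA_processed", arm.record_id, "", toy.fetch(iv), single(iv))
        )

    # GENCODE small genes: uniform gene choice, 20-40 nt fragments
    for gene_type in ("snoRNA", "rRNA", "miscRNA", "snRNA"):
        genes = [r for r in toy.gencode if r.metadata["gene_type"] == gene_type]
        for _ in range(class_counts.get(gene_type, 0)):
            gene = genes[rng.integers(0, len(genes))]
            glen = gene.end - gene.start
            ln = int(rng.integers(20, min(41, glen + 1)))
            off = int(rng.integers(0, glen - ln + 1))
            iv = GenomicInterval(gene.chrom, gene.start + off, gene.start + off + ln, gene.strand)
            reads.append(
                SimulatedRead(new_id(), name, gene_type, gene.record_id, "", toy.fetch(iv), single(iv))
            )

    # tRNA: fragment composition per condition, anticodon weights per tissue
    comp = config.fragment_composition[condition]
    frag_counts = _largest_remainder(comp, class_counts.get("tRNA", 0))
    anticodons = [r.metadata["anticodon"] for r in toy.trna]
    w_trna = _trna_weights(tissue, condition, anticodons)
    for frag_class, n_frag in sorted(frag_counts.items()):
        for _ in range(n_frag):
            gene = toy.trna[rng.choice(len(toy.trna), p=w_trna)]
            glen = gene.end - gene.start
            if frag_class == "five_prime_half":
                ln = int(rng.integers(31, 36))  # 33 +/- 2
                lo, hi = 0, ln
            elif frag_class == "full_length":
                ln = int(rng.integers(70, glen + 1))
                lo, hi = 0, ln
            else:  # interior fragment
                ln = int(rng.integers(20, 28))
                lo = int(rng.integers(10, glen - ln - 5))
                hi = lo + ln
            if gene.strand == "+":
                iv = GenomicInterval(gene.chrom, gene.start + lo, gene.start + hi, "+")
            else:
                iv = GenomicInterval(gene.chrom, gene.end - hi, gene.end - lo, "-")
            reads.append(
                SimulatedRead(new_id(), name, "tRNA", gene.record_id, frag_class, toy.fetch(iv), single(iv))
            )

    # piRNA: 26-31 nt inside a cluster
    for _ in range(class_counts.get("piRNA", 0)):
        cluster = toy.pirna[rng.integers(0, len(toy.pirna))]
        civ = cluster.intervals[0]
        ln = int(rng.integers(26, 32))
        off = int(rng.integers(0, len(civ) - ln + 1))
        iv = GenomicInterval(civ.chrom, civ.start + off, civ.start + off + ln, civ.strand)
        reads.append(
            SimulatedRead(new_id(), name, "piRNA", cluster.record_id, "", toy.fetch(iv), single(iv))
        )

    # repeats: a window of one family's consensus, placed in every copy
    families = {}
    for rec in toy.repeats:
        if rec.record_id.endswith(("_mir", "_snord")):
            continue  # annotation-only overlap copies
        families.setdefault(rec.name, []).append(rec)
    family_names = sorted(families)
    for _ in range(class_counts.get("repeat", 0)):
        fam = families[family_names[rng.integers(0, len(family_names))]]
        ln = int(rng.integers(25, 36))
        off = int(rng.integers(0, 300 - ln + 1))
        placements = [
            GenomicInterval("chrT", rec.start + off, rec.start + off + ln, "+") for rec in fam
        ]
        insert = chrT[placements[0].start : placements[0].end]
        reads.append(
            SimulatedRead(new_id(), name, "repeat", fam[0].name, "", insert, placements)
        )

    # unannotated: reads from a bare genomic region
    for _ in range(class_counts.get("unannotated", 0)):
        ln = int(rng.integers(20, 41))
        off = int(rng.integers(90000, 98000 - ln))
        iv = GenomicInterval("chrT", off, off + ln, "+")
        reads.append(
            SimulatedRead(new_id(), name, "Unannotated", "", "", toy.fetch(iv), single(iv))
        )

    return SimulatedSample(name, condition, tissue, reads)


def simulate_reads(
    config: SimulationConfig | None = None, toy: ToyGenome | None = None
) -> tuple[ToyGenome, list[SimulatedSample]]:
    """Simulate the full design; returns the genome and one object per sample."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    if toy is None:
        toy = build_toy_genome(config, rng)
    samples = [
        simulate_sample(config, toy, name, condition, tissue, rng)
        for name, condition, tissue in config.samples
    ]
    return toy, samples


# ---------------------------------------------------------------------------
# File emission


def write_sample_files(
    sample: SimulatedSample, toy: ToyGenome, outdir: str | Path, adapter: str = DEFAULT_ADAPTER
) -> dict[str, Path]:
    """Write FASTQ (insert + adapter), ground-truth SAM and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq": outdir / f"{sample.name}.fastq",
        "sam": outdir / f"{sample.name}.sam",
        "truth": outdir / f"{sample.name}.truth.tsv",
    }
    with open(paths["fastq"], "w") as out:
        for read in sample.reads:
            seq = read.insert + adapter
            out.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(paths["sam"], "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(toy.sequences):
            out.write(f"@SQ\tSN:{chrom}\tLN:{len(toy.sequences[chrom])}\n")
        for read in sample.reads:
            for k, iv in enumerate(read.placements):
                flag = 0 if iv.strand == "+" else 16
                if k > 0:
                    flag |= 256
                ref_seq = toy.sequences[iv.chrom][iv.start : iv.end]
                out.write(
                    f"{read.read_id}\t{flag}\t{iv.chrom}\t{iv.start + 1}\t255\t"
                    f"{len(iv)}M\t*\t0\t0\t{ref_seq}\t*\tAS:i:0\tNM:i:0\n"
                )
    with open(paths["truth"], "w") as out:
        out.write("read_id\tsample\trna_class\tgene_id\tfragment_class\n")
        for read in sample.reads:
            out.write(
                f"{read.read_id}\t{read.sample}\t{read.rna_class}\t{read.gene_id}\t{read.fragment_class}\n"
            )
    return paths


def simulate_conservation(
    toy: ToyGenome,
    rng: np.random.Generator | None = None,
    background_mean: float = 1.0,
    background_sd: float = 0.3,
    planted_offset: float = 2.0,
) -> dict[str, np.ndarray]:
    """Per-base conservation over chrU: noisy background, elevated planted sites.

    The background mean is kept positive so the ratio-normalized
    conservation (hit mean over UTR mean) is well behaved.
    """
    rng = rng or np.random.default_rng(0)
    track = {
        "chrU": rng.normal(background_mean, background_sd, size=len(toy.sequences["chrU"]))
    }
    for site in toy.planted_sites:
        track[site["chrom"]][site["start"] : site["end"]] += planted_offset
    return track


def write_conservation_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as out:
        for chrom in sorted(track):
            for pos, value in enumerate(track[chrom]):
                out.write(f"{chrom}\t{pos}\t{pos + 1}\t{value:.4f}\n")


def simulate_trna_fragment_mix(
    gene: AnnotationRecord,
    n_reads: int,
    five_prime_share: float = 0.7,
    rng: np.random.Generator | None = None,
) -> list[Alignment]:
    """Alignments for one tRNA gene: 33-nt 5' halves vs full-length reads.

    Exactly ``round(n_reads * five_prime_share)`` reads are 33-nt 5'
    halves; the rest cover the gene end to end (70+ nt).
    """
    rng = rng or np.random.default_rng(0)
    n_half = round(n_reads * five_prime_share)
    alignments = []
    glen = gene.end - gene.start
    for i in range(n_reads):
        if i < n_half:
            lo, hi = 0, 33
        else:
            lo, hi = 0, glen
        if gene.strand == "+":
            iv = GenomicInterval(gene.chrom, gene.start + lo, gene.start + hi, "+")
        else:
            iv = GenomicInterval(gene.chrom, gene.end - hi, gene.end - lo, "-")
        alignments.append(Alignment(f"frag_r{i:05d}", iv, 0.0, 0))
    return alignments
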