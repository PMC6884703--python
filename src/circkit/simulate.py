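"""Synthetic genomes, annotations, and junction evidence with ground truth.

The generator emulates the evidence the pipeline consumes downstream of
alignment: multi-exon genes with canonical GT/GC..AG intron motifs on a
random genome, planted circRNAs with per-sample head-to-tail chimeric
records (including coordinate-identical PCR duplicates), linear
splice-junction support, external-caller-style candidate files, and
artifact junctions in four categories (span above the filter limit,
non-canonical splice motifs, junctions spanning two disjoint genes, and
single-read support). Reads are represented at the junction-evidence
level, not as FASTQ; the scope of the toolkit starts after alignment.

Everything derives from a single integer seed through one ``random.Random``
stream, so a fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import quantify
from .core import (
    BackspliceJunction,
    ChimericRecord,
    CircCandidate,
    CircRecord,
    ExonInterval,
    GenomeSequence,
    LinearJunctionRecord,
    RepeatFeature,
    SampleLibrary,
    Strand,
    TranscriptModel,
    reverse_complement,
)
from .filters import FilterConfig

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "SimulatedDataset",
    "simulate_genome",
    "plant_circ_evidence",
    "simulate_dataset",
    "evaluate_against_truth",
    "TruthEvaluation",
]

TRUE_CIRC = "true_circ"
ARTIFACT_CATEGORIES = ("long_span", "non_canonical_motif", "multi_gene", "low_support")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a compact genome (20 genes of 4-8 exons across a
    handful of contigs) with 30 planted circRNAs, five artifacts per
    category and four samples split over two conditions -- large enough
    to exercise every filter rule, small enough to run in seconds.
    """

    seed: int = 0
    n_genes: int = 20
    genes_per_contig: int = 5
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (500, 2000)
    intergenic_gap: tuple[int, int] = (2000, 5000)
    gc_donor_fraction: float = 0.1
    n_circ: int = 30
    distinct_reads: tuple[int, int] = (2, 8)
    duplicate_rate: float = 0.2
    linear_reads: tuple[int, int] = (0, 20)
    artifacts: dict[str, int] = field(
        default_factory=lambda: {c: 5 for c in ARTIFACT_CATEGORIES}
    )
    n_cross_contig_records: int = 5
    n_samples: int = 4
    conditions: tuple[str, ...] = ("normoxia", "normoxia", "hypoxia", "hypoxia")
    library_size: int = 1_000_000
    segment_length: int = 35
    long_span_nt: tuple[int, int] = (100_001, 105_000)
    inverted_repeat_length: int = 50
    n_inverted_repeat_circ: int = 5
    n_same_orientation_circ: int = 3
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self):
        for lo, hi in (
            self.exons_per_gene,
            self.exon_length,
            self.intron_length,
            self.intergenic_gap,
            self.distinct_reads,
            self.linear_reads,
            self.long_span_nt,
        ):
            if lo > hi:
                raise ValueError("ranges must be non-empty (lo <= hi)")
        if self.exons_per_gene[0] < 4:
            raise ValueError("genes need >= 4 exons to host internal-exon circles")
        if len(self.conditions) != self.n_samples:
            raise ValueError("one condition label per sample required")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class TruthEntry:
    contig: str
    start: int
    end: int
    strand: Strand
    category: str
    all_reads: dict[str, int] = field(default_factory=dict)
    distinct_reads: dict[str, int] = field(default_factory=dict)
    linear_support: dict[str, float] = field(default_factory=dict)
    expected_fate: str = ""
    planted_repeat: str = "none"  # none / inverted / same

    @property
    def key(self):
        return (self.contig, self.start, self.end, self.strand)

    @property
    def junction(self) -> BackspliceJunction:
        return BackspliceJunction(self.contig, self.start, self.end, self.strand)


def predict_fate(entry: TruthEntry, config: FilterConfig) -> str:
    """Deterministic post-filter fate from category, counts, and config.

    Mirrors the fixed rule order of the filter cascade: span -> motif ->
    multi-gene -> support.
    """
    if entry.end - entry.start > config.max_span_nt:
        return "rejected:span"
    if entry.category == "non_canonical_motif":
        return "rejected:motif"
    if entry.category == "multi_gene" and config.exclude_multi_gene:
        return "rejected:multi_gene"
    n_ok = sum(
        1 for n in entry.distinct_reads.values() if n >= config.min_distinct_reads
    )
    if n_ok < config.min_samples_with_min_reads:
        return "rejected:support"
    return "retained"


# ---------------------------------------------------------------------------
# Genome + annotation


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, list[TranscriptModel]]:
    """Random genome plus one canonical transcript model per gene.

    Every annotated intron begins with GT (or GC at ``gc_donor_fraction``)
    and ends with AG on the template strand; genes alternate strand in
    pairs so each contig carries adjacent same-strand genes (needed to
    plant multi-gene artifacts). A dedicated gene-free long contig hosts
    the long-span artifacts.
    """
    rng = random.Random(config.seed)
    contigs: dict[str, str] = {}
    models: list[TranscriptModel] = []
    gene_idx = 0
    n_contigs = -(-config.n_genes // config.genes_per_contig) if config.n_genes else 0
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq: list[str] = []
        pos = 0
        genes_here = min(config.genes_per_contig, config.n_genes - gene_idx)
        for gi in range(genes_here):
            gap = rng.randint(*config.intergenic_gap)
            seq.append(_random_seq(rng, gap))
            pos += gap
            strand = Strand.PLUS if (gi % 4) < 2 else Strand.MINUS
            gene_seq, exons = _build_gene(rng, config, name, pos, strand)
            seq.append(gene_seq)
            pos += len(gene_seq)
            gene_id = f"SIMG{gene_idx + 1:03d}"
            models.append(
                TranscriptModel(
                    transcript_id=f"SIMT{gene_idx + 1:03d}",
                    gene_id=gene_id,
                    gene_name=f"Gene{gene_idx + 1}",
                    contig=name,
                    strand=strand,
                    exons=exons,
                    canonical_flag=True,
                    support_level=1,
                    cds_intervals=_default_cds(exons, strand),
                )
            )
            gene_idx += 1
        tail = rng.randint(*config.intergenic_gap)
        seq.append(_random_seq(rng, tail))
        contigs[name] = "".join(seq)
    if config.artifacts.get("long_span", 0) > 0:
        contigs["chrLong"] = _random_seq(rng, config.long_span_nt[1] + 2000)
    return GenomeSequence(contigs), models


def _default_cds(exons: list[ExonInterval], strand: Strand) -> list[tuple[int, int]]:
    """CDS covering the internal exons fully plus half of each terminal
    exon, leaving the outer halves as 5'/3' UTR."""
    genomic = sorted(exons, key=lambda e: e.start)
    if len(genomic) == 1:
        e = genomic[0]
        quarter = e.length // 4
        return [(e.start + quarter, e.end - quarter)]
    first, last = genomic[0], genomic[-1]
    cds = [(first.start + first.length // 2, first.end)]
    cds += [(e.start, e.end) for e in genomic[1:-1]]
    cds.append((last.start, last.start + last.length // 2))
    return cds


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _build_gene(
    rng: random.Random,
    config: SimulationConfig,
    contig: str,
    offset: int,
    strand: Strand,
) -> tuple[str, list[ExonInterval]]:
    n_exons = rng.randint(*config.exons_per_gene)
    pieces: list[str] = []
    exons: list[ExonInterval] = []
    pos = offset
    for i in range(n_exons):
        exon_len = rng.randint(*config.exon_length)
        pieces.append(_random_seq(rng, exon_len))
        exons.append(ExonInterval(contig, pos, pos + exon_len, rank=1))
        pos += exon_len
        if i < n_exons - 1:
            intron_len = rng.randint(*config.intron_length)
            body = _random_seq(rng, intron_len - 4)
            gc = rng.random() < config.gc_donor_fraction
            if strand is Strand.PLUS:
                donor = "GC" if gc else "GT"
                pieces.append(donor + body + "AG")
            else:
                # template-strand motifs mirrored onto the plus strand
                donor2 = "GC" if gc else "AC"  # revcomp(GC)=GC, revcomp(GT)=AC
                pieces.append("CT" + body + donor2)
            pos += intron_len
    return "".join(pieces), exons


# ---------------------------------------------------------------------------
# Evidence planting


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    libraries: list[SampleLibrary]
    chimeric: dict[str, list[ChimericRecord]]
    linear: dict[str, list[LinearJunctionRecord]]
    findcirc_candidates: list[CircCandidate]
    circexplorer_candidates: list[CircCandidate]
    repeats: list[RepeatFeature]
    truth: list[TruthEntry]

    def all_chimeric(self) -> list[ChimericRecord]:
        return [r for s in self.config.sample_ids for r in self.chimeric[s]]

    def all_linear(self) -> list[LinearJunctionRecord]:
        return [r for s in self.config.sample_ids for r in self.linear[s]]

    def write(self, outdir) -> dict[str, object]:
        """Write FASTA, GTF, per-sample junction/SJ tables, caller files,
        repeats, library table and the truth TSV; returns the path map."""
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, object] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["gtf"] = outdir / "annotation.gtf"
        write_gtf(self.transcripts, paths["gtf"])
        paths["chimeric"] = {}
        paths["sj"] = {}
        for s in self.config.sample_ids:
            pc = outdir / f"{s}.Chimeric.out.junction"
            write_chimeric_table(self.chimeric[s], pc)
            paths["chimeric"][s] = pc
            ps = outdir / f"{s}.SJ.out.tab"
            write_sj_table(self.linear[s], ps)
            paths["sj"][s] = ps
        paths["findcirc"] = outdir / "findcirc.bed"
        write_findcirc(self.findcirc_candidates, paths["findcirc"])
        paths["circexplorer"] = outdir / "circexplorer.txt"
        write_circexplorer(self.circexplorer_candidates, paths["circexplorer"])
        paths["repeats"] = outdir / "repeats.tsv"
        write_repeats(self.repeats, paths["repeats"])
        paths["libraries"] = outdir / "libraries.tsv"
        with open(paths["libraries"], "w") as fh:
            for lib in self.libraries:
                fh.write(f"{lib.sample_id}\t{lib.condition}\t{lib.library_size}\n")
        paths["truth"] = outdir / "truth.tsv"
        write_truth(self.truth, self.config.sample_ids, paths["truth"])
        return paths


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Convenience wrapper: genome + annotation + planted evidence."""
    if config is None:
        config = SimulationConfig()
    genome, models = simulate_genome(config)
    return plant_circ_evidence(genome, models, config)


def plant_circ_evidence(
    genome: GenomeSequence,
    models: list[TranscriptModel],
    config: SimulationConfig,
) -> SimulatedDataset:
    """Plant circRNAs, artifacts, read evidence and ground truth."""
    rng = random.Random(config.seed + 1_000_003)
    samples = config.sample_ids
    libraries = [
        SampleLibrary(s, config.conditions[i], config.library_size)
        for i, s in enumerate(samples)
    ]

    # --- choose junctions ---------------------------------------------------
    used: set[tuple] = set()
    combos = _single_gene_combos(models)
    rng.shuffle(combos)
    need = config.n_circ + config.artifacts.get("low_support", 0) + config.artifacts.get(
        "non_canonical_motif", 0
    )
    if len(combos) < need:
        raise ValueError(
            f"gene structures support only {len(combos)} distinct junctions, "
            f"need {need}; increase genes or exons per gene"
        )
    truth: list[TruthEntry] = []

    def take_combo():
        while combos:
            model, a, d = combos.pop()
            j = _junction_for_ranks(model, a, d)
            if j.key not in used:
                used.add(j.key)
                return model, a, d, j
        raise ValueError("exhausted junction combinations")

    genome_mut = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    repeats: list[RepeatFeature] = []

    planted_intervals: list[tuple[str, int, int]] = []
    for i in range(config.n_circ):
        model, a, d, j = take_combo()
        distinct = {s: rng.randint(*config.distinct_reads) for s in samples}
        entry = TruthEntry(j.contig, j.start, j.end, j.strand, TRUE_CIRC, distinct_reads=distinct)
        if i < config.n_inverted_repeat_circ:
            if _plant_inverted_repeat(rng, genome_mut, repeats, j, config,
                                      inverted=True, occupied=planted_intervals):
                entry.planted_repeat = "inverted"
        elif i < config.n_inverted_repeat_circ + config.n_same_orientation_circ:
            if _plant_inverted_repeat(rng, genome_mut, repeats, j, config,
                                      inverted=False, occupied=planted_intervals):
                entry.planted_repeat = "same"
        truth.append(entry)

    for _ in range(config.artifacts.get("low_support", 0)):
        model, a, d, j = take_combo()
        distinct = {s: 0 for s in samples}
        distinct[rng.choice(samples)] = 1
        truth.append(
            TruthEntry(j.contig, j.start, j.end, j.strand, "low_support", distinct_reads=distinct)
        )

    for _ in range(config.artifacts.get("non_canonical_motif", 0)):
        # A strand-flipped junction at genuine exon boundaries reads the
        # motif from the wrong strand, which is deterministically
        # non-canonical (revcomp of AG/GT context).
        model, a, d, j = take_combo()
        flipped = BackspliceJunction(j.contig, j.start, j.end, j.strand.flip())
        used.add(flipped.key)
        distinct = {s: rng.randint(*config.distinct_reads) for s in samples}
        truth.append(
            TruthEntry(
                flipped.contig, flipped.start, flipped.end, flipped.strand,
                "non_canonical_motif", distinct_reads=distinct,
            )
        )

    for pair_i in range(config.artifacts.get("multi_gene", 0)):
        j = _multi_gene_junction(models, config, rng, used)
        used.add(j.key)
        distinct = {s: rng.randint(*config.distinct_reads) for s in samples}
        truth.append(
            TruthEntry(j.contig, j.start, j.end, j.strand, "multi_gene", distinct_reads=distinct)
        )

    if config.artifacts.get("long_span", 0) > 0:
        contig = "chrLong"
        length = genome.contig_length(contig)
        for i in range(config.artifacts["long_span"]):
            while True:
                span = rng.randint(*config.long_span_nt)
                start = rng.randint(10, length - span - 10)
                j = BackspliceJunction(contig, start, start + span, Strand.PLUS)
                if j.key not in used:
                    break
            used.add(j.key)
            distinct = {s: rng.randint(*config.distinct_reads) for s in samples}
            truth.append(
                TruthEntry(j.contig, j.start, j.end, j.strand, "long_span", distinct_reads=distinct)
            )

    genome = GenomeSequence({name: bytes(b).decode("ascii") for name, b in genome_mut.items()})

    # --- emit chimeric records ----------------------------------------------
    chimeric: dict[str, list[ChimericRecord]] = {s: [] for s in samples}
    read_no = 0
    for entry in truth:
        j = entry.junction
        if j.strand is Strand.PLUS:
            donor_site, acceptor_site = j.end, j.start - 1
        else:
            donor_site, acceptor_site = j.start - 1, j.end
        for s in samples:
            n_distinct = entry.distinct_reads[s]
            n_all = 0
            for k in range(n_distinct):
                read_no += 1
                rec = ChimericRecord(
                    read_id=f"read{read_no:07d}",
                    contig=j.contig,
                    strand=j.strand,
                    donor_site=donor_site,
                    acceptor_site=acceptor_site,
                    junction_motif_code=0,
                    seg1_pos=max(j.end - config.segment_length - k, j.start),
                    seg1_cigar=f"{config.segment_length}M",
                    seg2_pos=j.start + k,
                    seg2_cigar=f"{config.segment_length}M",
                    sample_id=s,
                )
                chimeric[s].append(rec)
                n_all += 1
                n_dups = int(rng.random() < config.duplicate_rate)
                if entry.category == "low_support" and n_distinct == 1:
                    n_dups = 1  # exercise coordinate-keyed dedup on the boundary case
                for _ in range(n_dups):
                    read_no += 1
                    chimeric[s].append(
                        ChimericRecord(
                            read_id=f"read{read_no:07d}",
                            contig=rec.contig,
                            strand=rec.strand,
                            donor_site=rec.donor_site,
                            acceptor_site=rec.acceptor_site,
                            junction_motif_code=0,
                            seg1_pos=rec.seg1_pos,
                            seg1_cigar=rec.seg1_cigar,
                            seg2_pos=rec.seg2_pos,
                            seg2_cigar=rec.seg2_cigar,
                            sample_id=s,
                        )
                    )
                    n_all += 1
            entry.all_reads[s] = n_all

    contig_names = [c for c in genome.contig_names() if c != "chrLong"]
    for i in range(config.n_cross_contig_records):
        read_no += 1
        c1, c2 = rng.sample(contig_names, 2) if len(contig_names) >= 2 else (None, None)
        if c1 is None:
            break
        chimeric[samples[i % len(samples)]].append(
            ChimericRecord(
                read_id=f"read{read_no:07d}",
                contig=c1,
                strand=Strand.PLUS,
                donor_site=rng.randint(100, 1000),
                acceptor_site=rng.randint(100, 1000),
                junction_motif_code=-1,
                seg1_pos=rng.randint(100, 1000),
                seg1_cigar=f"{config.segment_length}M",
                seg2_pos=rng.randint(100, 1000),
                seg2_cigar=f"{config.segment_length}M",
                sample_id=samples[i % len(samples)],
                acceptor_contig=c2,
            )
        )

    for s in samples:
        rng.shuffle(chimeric[s])

    # --- linear junction support --------------------------------------------
    linear: dict[str, list[LinearJunctionRecord]] = {s: [] for s in samples}
    for model in models:
        for intron_start, intron_end in model.introns():
            for s in samples:
                linear[s].append(
                    LinearJunctionRecord(
                        contig=model.contig,
                        intron_start=intron_start,
                        intron_end=intron_end,
                        strand=model.strand,
                        unique_reads=rng.randint(*config.linear_reads),
                        multi_reads=0,
                        annotated_flag=True,
                        sample_id=s,
                    )
                )
    for entry in truth:
        for s in samples:
            entry.linear_support[s] = quantify.linear_support(entry.junction, linear[s])

    for entry in truth:
        entry.expected_fate = predict_fate(entry, config.filter_config)

    # --- caller-style candidate lists ---------------------------------------
    findcirc = [
        CircCandidate(
            e.contig, e.start, e.end, e.strand,
            provenance=frozenset({"finder_A"}),
            reported_counts=(("finder_A", sum(e.all_reads.values())),),
        )
        for e in truth
        if e.category in (TRUE_CIRC, "long_span")
    ]
    circexplorer = [
        CircCandidate(
            e.contig, e.start, e.end, e.strand,
            provenance=frozenset({"finder_B"}),
            reported_counts=(("finder_B", sum(e.all_reads.values())),),
        )
        for e in truth
        if e.category in (TRUE_CIRC, "multi_gene")
    ]

    return SimulatedDataset(
        config=config,
        genome=genome,
        transcripts=models,
        libraries=libraries,
        chimeric=chimeric,
        linear=linear,
        findcirc_candidates=findcirc,
        circexplorer_candidates=circexplorer,
        repeats=repeats,
        truth=truth,
    )


def _single_gene_combos(models: list[TranscriptModel]) -> list[tuple[TranscriptModel, int, int]]:
    """(model, acceptor rank, donor rank) choices with internal boundaries.

    Acceptor rank >= 2 and donor rank <= n-1 guarantee a flanking intron
    on each side, hence canonical planted motifs at both boundaries.
    """
    combos = []
    for m in models:
        for a in range(2, m.n_exons):
            for d in range(a, m.n_exons):
                combos.append((m, a, d))
    return combos


def _junction_for_ranks(model: TranscriptModel, a: int, d: int) -> BackspliceJunction:
    acceptor_exon = model.exons[a - 1]
    donor_exon = model.exons[d - 1]
    if model.strand is Strand.PLUS:
        start, end = acceptor_exon.start, donor_exon.end
    else:
        start, end = donor_exon.start, acceptor_exon.end
    return BackspliceJunction(model.contig, start, end, model.strand)


def _multi_gene_junction(
    models: list[TranscriptModel],
    config: SimulationConfig,
    rng: random.Random,
    used: set,
) -> BackspliceJunction:
    """Junction whose acceptor lies in one + gene and donor in the next,
    disjoint, + gene on the same contig."""
    by_contig: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if m.strand is Strand.PLUS:
            by_contig.setdefault(m.contig, []).append(m)
    pairs = []
    for contig, genes in sorted(by_contig.items()):
        genes.sort(key=lambda m: m.genomic_start)
        pairs.extend(zip(genes, genes[1:]))
    rng.shuffle(pairs)
    for left, right in pairs:
        a_choices = list(range(2, left.n_exons + 1))
        d_choices = list(range(1, right.n_exons))
        rng.shuffle(a_choices)
        rng.shuffle(d_choices)
        for a in a_choices:
            for d in d_choices:
                start = left.exons[a - 1].start
                end = right.exons[d - 1].end
                if end - start > config.filter_config.max_span_nt:
                    continue
                j = BackspliceJunction(left.contig, start, end, Strand.PLUS)
                if j.key not in used:
                    return j
    raise ValueError("no same-strand adjacent gene pair available for multi-gene artifact")


def _plant_inverted_repeat(
    rng: random.Random,
    genome_mut: dict[str, bytearray],
    repeats: list[RepeatFeature],
    junction: BackspliceJunction,
    config: SimulationConfig,
    inverted: bool,
    occupied: list[tuple[str, int, int]],
) -> bool:
    """Write a repeat into both flanking introns and record Alu-like
    annotation features; inverted pairs get reverse-complemented copies on
    opposite strands. Skips (returns False) when a window would overwrite
    a previously planted repeat."""
    length = config.inverted_repeat_length
    margin = 150  # clear of the splice-site dinucleotides and exon edges
    up_start = junction.start - margin - length
    down_start = junction.end + margin
    if up_start < 0 or down_start + length > len(genome_mut[junction.contig]):
        return False
    for iv in ((junction.contig, up_start, up_start + length),
               (junction.contig, down_start, down_start + length)):
        for c, s, e in occupied:
            if c == iv[0] and s < iv[2] and e > iv[1]:
                return False
    repeat_seq = _random_seq(rng, length)
    buf = genome_mut[junction.contig]
    # A-padding on both sides pairs A against T after reverse
    # complementation, so the recovered local alignment is exactly the
    # planted repeat
    partner = reverse_complement(repeat_seq) if inverted else repeat_seq
    buf[up_start - 4 : up_start + length + 4] = b"AAAA" + repeat_seq.encode("ascii") + b"AAAA"
    buf[down_start - 4 : down_start + length + 4] = b"AAAA" + partner.encode("ascii") + b"AAAA"
    repeats.append(
        RepeatFeature(junction.contig, up_start, up_start + length, Strand.PLUS,
                      "AluYsim", "SINE/Alu")
    )
    repeats.append(
        RepeatFeature(
            junction.contig, down_start, down_start + length,
            Strand.MINUS if inverted else Strand.PLUS, "AluYsim", "SINE/Alu",
        )
    )
    occupied.append((junction.contig, up_start, up_start + length))
    occupied.append((junction.contig, down_start, down_start + length))
    return True


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class TruthEvaluation:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    leaked_by_category: dict[str, int]
    missed: list[tuple]


def evaluate_against_truth(
    filtered_catalog: list[CircRecord], truth: list[TruthEntry]
) -> TruthEvaluation:
    """Exact-coordinate precision/recall of a filtered catalog.

    A truth entry is positive when its expected post-filter fate is
    "retained". Retained junctions not expected (artifact leaks or
    spurious calls) are false positives, tallied per truth category.
    """
    expected = {e.key: e for e in truth}
    positives = {k for k, e in expected.items() if e.expected_fate == "retained"}
    retained = {r.key for r in filtered_catalog}
    tp = len(retained & positives)
    fp_keys = retained - positives
    fn_keys = positives - retained
    leaked: dict[str, int] = {}
    for k in fp_keys:
        cat = expected[k].category if k in expected else "unplanted"
        leaked[cat] = leaked.get(cat, 0) + 1
    return TruthEvaluation(
        precision=tp / (tp + len(fp_keys)) if retained else 1.0,
        recall=tp / (tp + len(fn_keys)) if positives else 1.0,
        tp=tp,
        fp=len(fp_keys),
        fn=len(fn_keys),
        leaked_by_category=leaked,
        missed=sorted(fn_keys),
    )


# ---------------------------------------------------------------------------
# File emitters (dialect writers used by SimulatedDataset.write)


def write_gtf(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.contig, m.genomic_start)):
            attrs = (
                f'gene_id "{m.gene_id}"; gene_name "{m.gene_name}"; '
                f'transcript_id "{m.transcript_id}"; '
                f'transcript_support_level "{m.support_level or 1}"; tag "canonical";'
            )
            fh.write(
                f"{m.contig}\tcircsim\tgene\t{m.genomic_start + 1}\t{m.genomic_end}\t.\t"
                f'{m.strand.value}\t.\tgene_id "{m.gene_id}"; gene_name "{m.gene_name}";\n'
            )
            fh.write(
                f"{m.contig}\tcircsim\ttranscript\t{m.genomic_start + 1}\t{m.genomic_end}\t.\t"
                f"{m.strand.value}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.contig}\tcircsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f'{m.strand.value}\t.\t{attrs} exon_number "{e.rank}";\n'
                )
            for s, e in m.cds_intervals:
                fh.write(
                    f"{m.contig}\tcircsim\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand.value}\t0\t{attrs}\n"
                )


def write_chimeric_table(records: list[ChimericRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            acceptor_contig = r.acceptor_contig or r.contig
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.contig, r.donor_site + 1, r.strand.value,
                            acceptor_contig, r.acceptor_site + 1, r.strand.value,
                            r.junction_motif_code, 0, 0, r.read_id,
                            r.seg1_pos + 1, r.seg1_cigar, r.seg2_pos + 1, r.seg2_cigar,
                        ],
                    )
                )
                + "\n"
            )


def write_sj_table(records: list[LinearJunctionRecord], path) -> None:
    code = {Strand.UNKNOWN: 0, Strand.PLUS: 1, Strand.MINUS: 2}
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.contig, r.intron_start)):
            fh.write(
                f"{r.contig}\t{r.intron_start + 1}\t{r.intron_end}\t{code[r.strand]}\t1\t"
                f"{int(r.annotated_flag)}\t{r.unique_reads}\t{r.multi_reads}\t35\n"
            )


def write_findcirc(candidates: list[CircCandidate], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            count = sum(n for _, n in c.reported_counts)
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tsim_circ_{i + 1}\t{count}\t"
                f"{c.strand.value}\tCIRCULAR,ANCHOR_UNIQUE\n"
            )


def write_circexplorer(candidates: list[CircCandidate], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            count = sum(n for _, n in c.reported_counts)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            c.contig, c.start, c.end, f"circ_{i + 1}/{count}", 0,
                            c.strand.value, c.start, c.end, "0,0,0", 1,
                            c.end - c.start, 0, count, "circRNA", "NA", "NA",
                        ],
                    )
                )
                + "\n"
            )


def write_repeats(repeats: list[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.strand.value}\t{r.repeat_name}\t{r.repeat_family}\n"
            )


def write_truth(truth: list[TruthEntry], samples: list[str], path) -> None:
    with open(path, "w") as fh:
        header = ["contig", "start", "end", "strand", "category", "expected_fate"]
        for s in samples:
            header += [f"all_reads:{s}", f"distinct_reads:{s}", f"linear_support:{s}"]
        fh.write("#" + "\t".join(header) + "\n")
        for e in truth:
            row = [e.contig, e.start, e.end, e.strand.value, e.category, e.expected_fate]
            for s in samples:
                row += [
                    e.all_reads.get(s, 0),
                    e.distinct_reads.get(s, 0),
                    e.linear_support.get(s, 0.0),
                ]
            fh.write("\t".join(map(str, row)) + "\n")
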