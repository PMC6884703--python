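"""Readers and writers for every external dialect the pipeline touches.

Everything is normalized on input to 0-based half-open coordinates with an
explicit strand (see :mod:`circkit.core`). Sources and their native
conventions:

* STAR-style ``Chimeric.out.junction`` — 1-based positions; classic
  14-column dialect or the later dialect with comment/header lines and
  extra columns (autodetected).
* STAR-style ``SJ.out.tab`` — 1-based inclusive intron intervals, numeric
  strand code.
* find_circ-style BED6+ — 0-based half-open, keyword flags in extra
  columns.
* CIRCexplorer-style BED12+ — 0-based half-open, read count in column 13
  when present.
* GTF gene annotation — 1-based inclusive (parsed with pyranges, which
  normalizes to 0-based).
* RepeatMasker tracks — UCSC rmsk TSV (0-based) or RepeatMasker ``.out``
  (1-based).
* The internal catalog TSV, which round-trips :class:`~circkit.core.CircRecord`.
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BackspliceJunction,
    ChimericRecord,
    CircAnnotation,
    CircCandidate,
    CircRecord,
    CrosslinkSite,
    ExonInterval,
    GenomeSequence,
    LinearJunctionRecord,
    MotifClass,
    RepeatFeature,
    SampleLibrary,
    SpliceStatus,
    Strand,
    TranscriptModel,
    sort_candidates,
)

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_chimeric_table",
    "read_linear_junctions",
    "read_caller_candidates",
    "read_gene_annotation",
    "read_repeats",
    "read_crosslink_bed",
    "read_library_table",
    "write_catalog",
    "read_catalog",
]


class ParseError(ValueError):
    """Raised for malformed input rows; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ParseError(path, 0, f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# STAR-style chimeric junction table

_CHIMERIC_MIN_COLS = 14


def read_chimeric_table(path, sample_id: str) -> Iterator[ChimericRecord]:
    """Stream chimeric alignment records from a junction table.

    Accepts the classic headerless 14-column dialect as well as the later
    dialect with ``#`` comment lines, a header line, and extra columns
    (detected by a non-numeric second field). Cross-contig rows are
    emitted with ``acceptor_contig`` set so callers can exclude them from
    back-splice calling.
    """
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not seen_data and not _is_int(fields[1]):
                continue  # header line of the extended dialect
            if len(fields) < _CHIMERIC_MIN_COLS:
                raise ParseError(
                    path, lineno, f"expected >= {_CHIMERIC_MIN_COLS} columns, got {len(fields)}"
                )
            seen_data = True
            try:
                donor_site = int(fields[1]) - 1
                acceptor_site = int(fields[4]) - 1
                motif_code = int(fields[6])
                seg1_pos = int(fields[10]) - 1
                seg2_pos = int(fields[12]) - 1
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric coordinate field: {exc}") from None
            try:
                strand = Strand.parse(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if seg1_pos < 0 or seg2_pos < 0:
                raise ParseError(path, lineno, "segment positions must be >= 1 (1-based)")
            seg1_cigar, seg2_cigar = fields[11], fields[13]
            if not seg1_cigar or not seg2_cigar:
                raise ParseError(path, lineno, "empty CIGAR string")
            donor_contig, acceptor_contig = fields[0], fields[3]
            yield ChimericRecord(
                read_id=fields[9],
                contig=donor_contig,
                strand=strand,
                donor_site=donor_site,
                acceptor_site=acceptor_site,
                junction_motif_code=motif_code,
                seg1_pos=seg1_pos,
                seg1_cigar=seg1_cigar,
                seg2_pos=seg2_pos,
                seg2_cigar=seg2_cigar,
                sample_id=sample_id,
                acceptor_contig=acceptor_contig if acceptor_contig != donor_contig else None,
            )


def _is_int(x: str) -> bool:
    try:
        int(x)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# SJ-style linear splice junction table


def read_linear_junctions(path, sample_id: str) -> Iterator[LinearJunctionRecord]:
    """Stream linear splice-junction counts from an SJ-dialect table.

    Source columns: contig, 1-based inclusive intron start/end, numeric
    strand code (0 unknown / 1 plus / 2 minus), motif code, annotated
    flag, unique-read count, multi-read count[, max overhang].
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(path, lineno, f"expected >= 8 columns, got {len(fields)}")
            try:
                start1 = int(fields[1])
                end1 = int(fields[2])
                annotated = int(fields[5])
                unique = int(fields[6])
                multi = int(fields[7])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric field in SJ row") from None
            if unique < 0 or multi < 0:
                raise ParseError(path, lineno, "negative read count")
            try:
                strand = Strand.parse(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            yield LinearJunctionRecord(
                contig=fields[0],
                intron_start=start1 - 1,
                intron_end=end1,  # inclusive 1-based end == exclusive 0-based end
                strand=strand,
                unique_reads=unique,
                multi_reads=multi,
                annotated_flag=bool(annotated),
                sample_id=sample_id,
            )


# ---------------------------------------------------------------------------
# External caller outputs

FINDCIRC_DIALECT = "findcirc_bed"
CIRCEXPLORER_DIALECT = "circexplorer_table"


def read_caller_candidates(
    path,
    dialect: str,
    required_keyword: str = "CIRCULAR",
) -> Iterator[CircCandidate]:
    """Stream circRNA candidates from an external caller's output file.

    ``findcirc_bed`` is BED6+ with a read-count score column and
    comma-separated keyword flags in the extra columns; rows lacking
    ``required_keyword`` are dropped. ``circexplorer_table`` is BED12+
    with the read count in column 13 when present, else the score column.
    """
    if dialect == FINDCIRC_DIALECT:
        provenance, source = frozenset({"finder_A"}), "finder_A"
    elif dialect == CIRCEXPLORER_DIALECT:
        provenance, source = frozenset({"finder_B"}), "finder_B"
    else:
        raise ValueError(f"unknown caller dialect {dialect!r}")

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            try:
                strand = Strand.parse(fields[5])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if dialect == FINDCIRC_DIALECT:
                if required_keyword and not any(
                    required_keyword in f.split(",") for f in fields[6:]
                ):
                    continue
                count = _parse_count(fields[4], path, lineno)
            else:
                count = _parse_count(
                    fields[12] if len(fields) > 12 else fields[4], path, lineno
                )
            yield CircCandidate(
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                provenance=provenance,
                reported_counts=((source, count),),
            )


def _parse_count(raw: str, path, lineno: int) -> int:
    try:
        count = int(float(raw))
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric read count {raw!r}") from None
    if count < 0:
        raise ParseError(path, lineno, "negative read count")
    return count


# ---------------------------------------------------------------------------
# GTF gene annotation


def read_gene_annotation(
    path,
    support_levels: Sequence[int] | None = (1, 2),
    canonical_ids: set[str] | None = None,
) -> list[TranscriptModel]:
    """Parse a GTF into transcript models with ranked exons.

    Transcripts whose support level is present and outside
    ``support_levels`` are dropped; transcripts without a support level
    pass by default. Canonical status comes from a GTF tag containing
    "canonical" or from the ``canonical_ids`` set.
    """
    import pyranges as pr

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = pr.read_gtf(str(path)).df
    if df.empty:
        return []

    def _attr(row, name):
        val = row.get(name)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        return val

    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[ExonInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        feature = row["Feature"]
        if feature not in ("transcript", "exon", "CDS"):
            continue
        tid = _attr(row, "transcript_id")
        if tid is None:
            if feature == "exon":
                raise ParseError(
                    path,
                    0,
                    "exon without parent transcript at "
                    f"{row['Chromosome']}:{row['Start']}-{row['End']}",
                )
            continue
        meta = tx_meta.setdefault(
            tid,
            {
                "gene_id": None,
                "gene_name": None,
                "contig": row["Chromosome"],
                "strand": Strand.parse(row["Strand"]),
                "support_level": None,
                "canonical": False,
            },
        )
        if meta["gene_id"] is None:
            meta["gene_id"] = _attr(row, "gene_id")
        if meta["gene_name"] is None:
            meta["gene_name"] = _attr(row, "gene_name")
        tsl = _attr(row, "transcript_support_level")
        if tsl is not None and meta["support_level"] is None:
            try:
                meta["support_level"] = int(str(tsl).split()[0])
            except ValueError:
                pass  # "NA" and friends
        tag = _attr(row, "tag")
        if tag is not None and "canonical" in str(tag).lower():
            meta["canonical"] = True
        if feature == "exon":
            exons.setdefault(tid, []).append(
                ExonInterval(row["Chromosome"], int(row["Start"]), int(row["End"]), rank=1)
            )
        elif feature == "CDS":
            cds.setdefault(tid, []).append((int(row["Start"]), int(row["End"])))

    models = []
    for tid, meta in tx_meta.items():
        if tid not in exons:
            continue
        level = meta["support_level"]
        if support_levels is not None and level is not None and level not in support_levels:
            continue
        canonical = meta["canonical"] or (canonical_ids is not None and tid in canonical_ids)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta["gene_id"] or tid,
                gene_name=meta["gene_name"] or meta["gene_id"] or tid,
                contig=meta["contig"],
                strand=meta["strand"],
                exons=exons[tid],
                canonical_flag=canonical,
                support_level=level,
                cds_intervals=sorted(cds.get(tid, [])),
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


# ---------------------------------------------------------------------------
# Repeat tracks


def read_repeats(path, family: str | None = None) -> list[RepeatFeature]:
    """Read a repeat track (UCSC rmsk TSV or RepeatMasker .out).

    ``family`` keeps only repeats whose family or name contains the given
    substring (e.g. "Alu"). Format is autodetected: ``.out`` files start
    with the RepeatMasker banner/score header and use 1-based coordinates,
    the UCSC TSV is tab-separated and 0-based.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    is_out = head.lstrip().lower().startswith(("sw", "score")) or path.suffix == ".out"
    feats: list[RepeatFeature] = []
    if is_out:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if len(fields) < 11 or not _is_int(fields[5]):
                    continue
                strand = Strand.MINUS if fields[8] in ("C", "-") else Strand.PLUS
                feats.append(
                    RepeatFeature(
                        contig=fields[4],
                        start=int(fields[5]) - 1,
                        end=int(fields[6]),
                        strand=strand,
                        repeat_name=fields[9],
                        repeat_family=fields[10],
                    )
                )
    else:
        # UCSC rmsk dump: genoName genoStart genoEnd strand repName repClass repFamily
        # either as the full 17-column table or a compact 7-column TSV.
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) >= 13 and _is_int(fields[6]):  # full rmsk schema
                    contig, start, end = fields[5], int(fields[6]), int(fields[7])
                    strand = Strand.parse(fields[9])
                    name, fam = fields[10], fields[12]
                elif len(fields) >= 6:
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = Strand.parse(fields[3])
                    name, fam = fields[4], fields[5]
                else:
                    raise ParseError(path, lineno, "unrecognized repeat table row")
                feats.append(RepeatFeature(contig, start, end, strand, name, fam))
    if family is not None:
        feats = [
            f for f in feats if family in f.repeat_family or family in f.repeat_name
        ]
    return feats


# ---------------------------------------------------------------------------
# Crosslink sites (BED6)


def read_crosslink_bed(path) -> list[CrosslinkSite]:
    """Read single-nucleotide crosslink sites from a BED6 file.

    The score column carries the per-site read count (defaults to 1 when
    "." or absent). Intervals wider than 1 nt are an error.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, "expected BED6")
            start, end = int(fields[1]), int(fields[2])
            if end - start != 1:
                raise ParseError(path, lineno, "crosslink sites must be single-nucleotide")
            score = fields[4]
            count = 1 if score in (".", "") else int(float(score))
            sites.append(
                CrosslinkSite(
                    contig=fields[0],
                    position=start,
                    strand=Strand.parse(fields[5]),
                    count=count,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Library-size table


def read_library_table(path) -> list[SampleLibrary]:
    """TSV with columns sample_id, condition, library_size."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample_id", "condition", "library_size"])
    return [
        SampleLibrary(str(r.sample_id), str(r.condition), int(r.library_size))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Internal catalog TSV

_CATALOG_FIXED = [
    "contig", "start", "end", "name", "score", "strand",
    "motif_class", "acceptor_status", "donor_status", "provenance",
]
_ANNOT_COLS = [
    "origin_class", "parental_transcript", "gene_id", "gene_name",
    "internal_exons", "acceptor_exon_rank", "donor_exon_rank",
    "acceptor_region", "donor_region", "upstream_intron_length",
    "downstream_intron_length", "spliced_length", "genomic_span",
]
_METRIC_PREFIXES = [
    ("all_reads", "all_reads"),
    ("distinct_reads", "distinct_reads"),
    ("linear_support", "linear_support"),
    ("rpm", "rpm"),
    ("clr", "clr"),
    ("pct_circ", "percent_circularized"),
]


def write_catalog(records: Iterable[CircRecord], path) -> None:
    """Write a catalog TSV with a BED6-compatible prefix.

    The first six columns are contig, start, end, name, distinct-read
    count (max over samples), strand in 0-based half-open coordinates.
    Per-sample metric columns are suffixed ``:<sample>``. Rows are sorted
    by (contig, start, end, strand) regardless of input order and the
    header documents the convention, so ``read_catalog`` round-trips.
    """
    records = sort_candidates(list(records))
    samples = sorted({s for r in records for s in r.all_reads} |
                     {s for r in records for s in r.distinct_reads} |
                     {s for r in records for s in r.linear_support})
    metric_cols = []
    for prefix, attr in _METRIC_PREFIXES:
        if any(getattr(r, attr) for r in records):
            metric_cols.extend((f"{prefix}:{s}", attr, s) for s in samples)
    has_annot = any(r.annotation is not None for r in records)
    columns = _CATALOG_FIXED + [c for c, _, _ in metric_cols]
    if has_annot:
        columns += _ANNOT_COLS

    with open(path, "w", newline="") as fh:
        fh.write("## circkit catalog; coordinates 0-based half-open; "
                 "columns 1-6 are BED6 (score = max per-sample distinct reads)\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#" + columns[0]] + columns[1:])
        for r in records:
            j = r.junction
            row = [
                j.contig, j.start, j.end, j.name, r.max_distinct(), j.strand.value,
                j.motif_class.value if j.motif_class else "",
                j.acceptor_status.value if j.acceptor_status else "",
                j.donor_status.value if j.donor_status else "",
                ",".join(sorted(r.provenance)),
            ]
            for _, attr, s in metric_cols:
                d = getattr(r, attr)
                if s not in d:
                    row.append("")
                elif d[s] is None:
                    row.append("NA")
                else:
                    row.append(repr(d[s]) if isinstance(d[s], float) else d[s])
            if has_annot:
                row.extend(_annotation_cells(r.annotation))
            writer.writerow(row)


def _annotation_cells(a: CircAnnotation | None) -> list:
    if a is None:
        return [""] * len(_ANNOT_COLS)
    return [
        a.origin_class,
        a.parental_transcript_id or "",
        a.gene_id or "",
        a.gene_name or "",
        ";".join(f"{e.start}-{e.end}:{e.rank}" for e in a.internal_exons),
        "" if a.acceptor_exon_rank is None else a.acceptor_exon_rank,
        "" if a.donor_exon_rank is None else a.donor_exon_rank,
        a.acceptor_region or "",
        a.donor_region or "",
        "" if a.upstream_intron_length is None else a.upstream_intron_length,
        "" if a.downstream_intron_length is None else a.downstream_intron_length,
        "" if a.spliced_length is None else a.spliced_length,
        "" if a.genomic_span is None else a.genomic_span,
    ]


def read_catalog(path) -> list[CircRecord]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("##")]
    if not lines:
        return []
    header = lines[0].lstrip("#").split("\t")
    idx = {c: i for i, c in enumerate(header)}
    metric_map = {prefix: attr for prefix, attr in _METRIC_PREFIXES}
    records = []
    for line in lines[1:]:
        if not line:
            continue
        f = line.split("\t")

        def cell(col):
            i = idx.get(col)
            return f[i] if i is not None and i < len(f) else ""

        junction = BackspliceJunction(
            contig=cell("contig"),
            start=int(cell("start")),
            end=int(cell("end")),
            strand=Strand.parse(cell("strand")),
            motif_class=MotifClass(cell("motif_class")) if cell("motif_class") else None,
            acceptor_status=SpliceStatus(cell("acceptor_status")) if cell("acceptor_status") else None,
            donor_status=SpliceStatus(cell("donor_status")) if cell("donor_status") else None,
        )
        rec = CircRecord(
            junction=junction,
            provenance=frozenset(cell("provenance").split(",")) - {""},
        )
        for col, i in idx.items():
            if ":" not in col:
                continue
            prefix, sample = col.split(":", 1)
            attr = metric_map.get(prefix)
            if attr is None:
                continue
            raw = f[i] if i < len(f) else ""
            if raw == "":
                continue
            d = getattr(rec, attr)
            if raw == "NA":
                d[sample] = None
            elif attr in ("all_reads", "distinct_reads"):
                d[sample] = int(raw)
            else:
                d[sample] = float(raw)
        if "origin_class" in idx and cell("origin_class"):
            rec.annotation = CircAnnotation(
                origin_class=cell("origin_class"),
                parental_transcript_id=cell("parental_transcript") or None,
                gene_id=cell("gene_id") or None,
                gene_name=cell("gene_name") or None,
                internal_exons=[
                    ExonInterval(junction.contig, int(p.split("-")[0]),
                                 int(p.split("-")[1].split(":")[0]),
                                 int(p.split(":")[1]))
                    for p in cell("internal_exons").split(";") if p
                ],
                acceptor_exon_rank=_opt_int(cell("acceptor_exon_rank")),
                donor_exon_rank=_opt_int(cell("donor_exon_rank")),
                acceptor_region=cell("acceptor_region") or None,
                donor_region=cell("donor_region") or None,
                upstream_intron_length=_opt_int(cell("upstream_intron_length")),
                downstream_intron_length=_opt_int(cell("downstream_intron_length")),
                spliced_length=_opt_int(cell("spliced_length")),
                genomic_span=_opt_int(cell("genomic_span")),
            )
        records.append(rec)
    return records


def _opt_int(raw: str) -> int | None:
    return int(raw) if raw else None
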