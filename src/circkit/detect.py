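"""Back-splice junction calling from chimeric alignment records.

A chimeric alignment supports a back-splice junction when both segments
map to the same contig and strand and the two splice sites are in
head-to-tail order: in transcript orientation the donor lies downstream
of the acceptor, so the circularized genomic span runs from the acceptor
exon's first base to the donor exon's last base.

Coordinate mapping (0-based, junction span half-open):

* ``+`` strand: span start = acceptor_site + 1 (first exonic base right of
  the acceptor-adjacent intronic base), span end = donor_site (the first
  intronic base 3' of the donor exon, i.e. the exclusive exon end).
* ``-`` strand: mirrored — span start = donor_site + 1, span end =
  acceptor_site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .core import (
    BackspliceJunction,
    ChimericRecord,
    GenomeSequence,
    MotifClass,
    SpliceStatus,
    Strand,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "CallStats",
    "call_junctions",
    "junction_from_record",
    "classify_motif",
    "annotate_splice_status",
    "cigar_reference_length",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def cigar_reference_length(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X operations)."""
    length = 0
    matched = 0
    for n, op in _CIGAR_RE.findall(cigar):
        matched += len(n) + 1
        if op in _REF_CONSUMING:
            length += int(n)
    if matched != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return length


def cigar_aligned_length(cigar: str) -> int:
    """Aligned (M/=/X) reference bases: the junction-flank overhang."""
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "M=X")


@dataclass
class CallStats:
    """Tally of chimeric records that did not qualify for junction calling."""

    total: int = 0
    qualifying: int = 0
    cross_contig: int = 0
    not_head_to_tail: int = 0
    short_overhang: int = 0
    bad_strand: int = 0
    strand_conflict_dropped: int = 0


def junction_from_record(record: ChimericRecord) -> BackspliceJunction | None:
    """Map a single head-to-tail chimeric record to its junction span.

    Returns None when the record is not a same-contig head-to-tail
    arrangement.
    """
    if record.cross_contig:
        return None
    if record.strand is Strand.PLUS:
        start, end = record.acceptor_site + 1, record.donor_site
    elif record.strand is Strand.MINUS:
        start, end = record.donor_site + 1, record.acceptor_site
    else:
        return None
    if start >= end or start < 0:
        return None
    return BackspliceJunction(record.contig, start, end, record.strand)


def call_junctions(
    records,
    min_overhang: int = 15,
    stats: CallStats | None = None,
) -> dict[BackspliceJunction, list[ChimericRecord]]:
    """Group qualifying chimeric records into back-splice junctions.

    Returns junctions in canonical order mapped to their supporting
    records. Non-qualifying records are tallied in ``stats`` rather than
    raising. Junctions whose support comes from records of conflicting
    strands at identical coordinates are dropped as inconsistencies.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if stats is None:
        stats = CallStats()
    by_junction: dict[BackspliceJunction, list[ChimericRecord]] = {}
    for rec in records:
        stats.total += 1
        if rec.cross_contig:
            stats.cross_contig += 1
            continue
        if rec.strand not in (Strand.PLUS, Strand.MINUS):
            stats.bad_strand += 1
            continue
        junction = junction_from_record(rec)
        if junction is None:
            stats.not_head_to_tail += 1
            continue
        overhang = min(
            cigar_aligned_length(rec.seg1_cigar), cigar_aligned_length(rec.seg2_cigar)
        )
        if overhang < min_overhang:
            stats.short_overhang += 1
            continue
        stats.qualifying += 1
        by_junction.setdefault(junction, []).append(rec)

    # Drop junctions supported by strand-conflicting evidence: the same
    # genomic span claimed on both strands is an alignment inconsistency.
    spans: dict[tuple[str, int, int], set[Strand]] = {}
    for j in by_junction:
        spans.setdefault((j.contig, j.start, j.end), set()).add(j.strand)
    out = {}
    for j in sorted(by_junction, key=lambda j: (j.contig, j.start, j.end, j.strand.value)):
        if len(spans[(j.contig, j.start, j.end)]) > 1:
            stats.strand_conflict_dropped += len(by_junction[j])
            continue
        out[j] = by_junction[j]
    return out


def classify_motif(junction: BackspliceJunction, genome: GenomeSequence) -> MotifClass:
    """Classify the splice-site dinucleotide pairing of a junction.

    On the + strand the donor dinucleotide is read at [end, end+2) and the
    acceptor at [start-2, start); on the - strand both are read as reverse
    complements from the opposite boundaries. GT..AG -> GT_AG, GC..AG ->
    GC_AG, anything else (including N) -> other.
    """
    j = junction
    if j.start < 2 or j.end + 2 > genome.contig_length(j.contig):
        raise IndexError(
            f"junction {j.name} within 2 nt of a contig boundary; motif undefined"
        )
    if j.strand is Strand.MINUS:
        donor = reverse_complement(genome.fetch(j.contig, j.start - 2, j.start))
        acceptor = reverse_complement(genome.fetch(j.contig, j.end, j.end + 2))
    else:
        donor = genome.fetch(j.contig, j.end, j.end + 2)
        acceptor = genome.fetch(j.contig, j.start - 2, j.start)
    if acceptor != "AG":
        return MotifClass.OTHER
    if donor == "GT":
        return MotifClass.GT_AG
    if donor == "GC":
        return MotifClass.GC_AG
    return MotifClass.OTHER


def annotate_splice_status(
    junction: BackspliceJunction, transcript_models: list[TranscriptModel]
) -> BackspliceJunction:
    """Mark each side of the junction as annotated or de novo.

    A side is annotated iff its boundary coincides exactly with an
    annotated exon boundary of matching type on the same contig and
    strand: the acceptor boundary with an exon start (in transcript
    orientation), the donor boundary with an exon end.
    """
    acceptor = SpliceStatus.DE_NOVO
    donor = SpliceStatus.DE_NOVO
    for model in transcript_models:
        if model.contig != junction.contig or model.strand != junction.strand:
            continue
        for exon in model.exons:
            # transcript-orientation exon start/end in genomic coordinates
            if model.strand is Strand.PLUS:
                exon_start, exon_end = exon.start, exon.end
            else:
                exon_start, exon_end = exon.end, exon.start
            if junction.strand is Strand.PLUS:
                if exon_start == junction.start:
                    acceptor = SpliceStatus.ANNOTATED
                if exon_end == junction.end:
                    donor = SpliceStatus.ANNOTATED
            else:
                if exon_start == junction.end:
                    acceptor = SpliceStatus.ANNOTATED
                if exon_end == junction.start:
                    donor = SpliceStatus.ANNOTATED
    return replace(junction, acceptor_status=acceptor, donor_status=donor)
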