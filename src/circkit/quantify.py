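"""Back-splice read recounting and abundance metrics.

After harmonizing candidate calls, support is recounted directly from the
chimeric alignments so every circRNA gets a consistent estimate
regardless of which caller reported it. PCR duplicates are flagged by
mapping coordinates (segment positions + CIGARs), not read sequence:
``distinct_reads`` drives presence thresholds while ``all_reads`` drives
abundance metrics.

Metrics per sample:

* RPM — back-splice reads per million mapped reads.
* linear support — mean unique-read count of linear introns sharing
  either splice site of the junction.
* CLR — circular-to-linear ratio, back / (linear + 1); the pseudocount
  stabilizes the denominator.
* percent circularized — 100 * back / (back + linear); undefined (None)
  when both are zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .core import (
    BackspliceJunction,
    ChimericRecord,
    CircRecord,
    LinearJunctionRecord,
    SampleLibrary,
    Strand,
    TranscriptModel,
)
from .detect import junction_from_record

__all__ = [
    "flag_duplicates",
    "count_backsplice",
    "rpm",
    "linear_support",
    "clr",
    "percent_circularized",
    "clr_shift",
    "host_tpm",
    "HostGeneExpression",
]


def flag_duplicates(
    records: list[ChimericRecord],
) -> tuple[list[tuple[ChimericRecord, bool]], int, int]:
    """Flag coordinate-based PCR duplicates within one sample's records.

    The duplicate key is (contig, strand, seg1_pos, seg1_cigar, seg2_pos,
    seg2_cigar); the first record per key is kept as non-duplicate, later
    ones are flagged. Returns (flagged records, all_reads, distinct_reads).
    """
    seen: set[tuple] = set()
    flagged = []
    for rec in records:
        key = rec.duplicate_key
        is_dup = key in seen
        seen.add(key)
        flagged.append((rec, is_dup))
    return flagged, len(flagged), len(seen)


def count_backsplice(
    catalog: list[BackspliceJunction],
    chimeric_records: list[ChimericRecord],
    libraries: list[SampleLibrary],
    min_overhang: int = 1,
) -> dict[tuple, CircRecord]:
    """Recount per-sample all/distinct back-splice reads for a catalog.

    Records are matched to catalog junctions by exact coordinates after
    the same head-to-tail mapping used at detection time. Junctions with
    zero support are retained with zero counts; a record from a sample
    absent from ``libraries`` is an error.
    """
    from .detect import cigar_aligned_length

    known_samples = {lib.sample_id for lib in libraries}
    wanted = {j.key: j for j in catalog}
    per_junction_sample: dict[tuple, dict[str, list[ChimericRecord]]] = {
        key: {} for key in wanted
    }
    for rec in chimeric_records:
        if rec.sample_id not in known_samples:
            raise KeyError(
                f"sample {rec.sample_id!r} in chimeric records but not in libraries"
            )
        j = junction_from_record(rec)
        if j is None or j.key not in wanted:
            continue
        if min(cigar_aligned_length(rec.seg1_cigar), cigar_aligned_length(rec.seg2_cigar)) < min_overhang:
            continue
        per_junction_sample[j.key].setdefault(rec.sample_id, []).append(rec)

    out: dict[tuple, CircRecord] = {}
    for key, junction in wanted.items():
        all_reads = {lib.sample_id: 0 for lib in libraries}
        distinct = {lib.sample_id: 0 for lib in libraries}
        for sample, recs in per_junction_sample[key].items():
            _, n_all, n_distinct = flag_duplicates(recs)
            all_reads[sample] = n_all
            distinct[sample] = n_distinct
        out[key] = CircRecord(
            junction=junction, all_reads=all_reads, distinct_reads=distinct
        )
    return out


def rpm(all_reads: int, library_size: int) -> float:
    """Back-splice reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return all_reads / library_size * 1e6


def linear_support(
    junction: BackspliceJunction, linear_records: list[LinearJunctionRecord]
) -> float:
    """Mean linear-junction read count over the two back-splice sites.

    For each boundary, linear introns sharing that exact splice site are
    summed (unique reads): on the + strand the acceptor at ``start``
    matches introns with intron_end == start and the donor at ``end``
    matches introns with intron_start == end; mirrored on the - strand.
    Splice sites with no linear junction contribute 0.
    """
    acceptor_sum = 0
    donor_sum = 0
    for rec in linear_records:
        if rec.contig != junction.contig:
            continue
        if rec.strand in (Strand.PLUS, Strand.MINUS) and rec.strand != junction.strand:
            continue
        if rec.intron_end == junction.start:
            acceptor_sum += rec.unique_reads if junction.strand is Strand.PLUS else 0
            donor_sum += rec.unique_reads if junction.strand is Strand.MINUS else 0
        if rec.intron_start == junction.end:
            donor_sum += rec.unique_reads if junction.strand is Strand.PLUS else 0
            acceptor_sum += rec.unique_reads if junction.strand is Strand.MINUS else 0
    return (acceptor_sum + donor_sum) / 2.0


def clr(all_reads: float, linear: float) -> float:
    """Circular-to-linear ratio with a +1 pseudocount on the denominator."""
    if all_reads < 0 or linear < 0:
        raise ValueError("inputs must be non-negative")
    return all_reads / (linear + 1.0)


def percent_circularized(all_reads: float, linear: float) -> float | None:
    """100 * back / (back + linear); None when both counts are zero."""
    if all_reads < 0 or linear < 0:
        raise ValueError("inputs must be non-negative")
    total = all_reads + linear
    if total == 0:
        return None
    return 100.0 * all_reads / total


def clr_shift(
    record: CircRecord,
    libraries: list[SampleLibrary],
    condition_a: str,
    condition_b: str,
) -> float:
    """Fold change of mean CLR between two conditions (B over A).

    Zero denominator with nonzero numerator -> +inf; both zero -> 1.0.
    """
    groups = {condition_a: [], condition_b: []}
    for lib in libraries:
        if lib.condition in groups and lib.sample_id in record.clr:
            groups[lib.condition].append(record.clr[lib.sample_id])
    for label, values in groups.items():
        if not values:
            raise KeyError(f"no samples with CLR values for condition {label!r}")
    mean_a = sum(groups[condition_a]) / len(groups[condition_a])
    mean_b = sum(groups[condition_b]) / len(groups[condition_b])
    if mean_a == 0:
        return 1.0 if mean_b == 0 else math.inf
    return mean_b / mean_a


def attach_metrics(
    records: list[CircRecord],
    libraries: list[SampleLibrary],
    linear_records: list[LinearJunctionRecord],
) -> list[CircRecord]:
    """Fill per-sample linear support, RPM, CLR and percent circularized."""
    by_sample: dict[str, list[LinearJunctionRecord]] = {}
    for rec in linear_records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    for record in records:
        for lib in libraries:
            back = record.all_reads.get(lib.sample_id, 0)
            linear = linear_support(
                record.junction, by_sample.get(lib.sample_id, [])
            )
            record.linear_support[lib.sample_id] = linear
            record.rpm[lib.sample_id] = rpm(back, lib.library_size)
            record.clr[lib.sample_id] = clr(back, linear)
            record.percent_circularized[lib.sample_id] = percent_circularized(back, linear)
    return records


@dataclass
class HostGeneExpression:
    gene_id: str
    tpm: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def host_tpm(
    exon_counts,
    transcript_models: list[TranscriptModel],
    circle_internal_exons: set[tuple[str, int, int]],
    exclude_internal_length: bool = True,
) -> dict[str, HostGeneExpression]:
    """Host-gene TPM with circle-internal exons excluded.

    ``exon_counts`` is a pandas DataFrame with columns gene_id, contig,
    start, end plus one column per sample. Reads on exons predicted to be
    internal to a circRNA are omitted so the circle does not inflate its
    host gene's estimate; by default the excluded exons' lengths are also
    removed from the effective gene length so the rate stays unbiased.

    TPM per sample: rate_g = counts_g / length_kb_g, TPM_g = rate_g /
    sum(rates) * 1e6. A gene whose every exon is internal gets TPM 0 with
    a warning.
    """
    known = {}
    for m in transcript_models:
        for e in m.exons:
            known.setdefault(m.gene_id, set()).add((e.contig, e.start, e.end))
    sample_cols = [
        c for c in exon_counts.columns if c not in ("gene_id", "contig", "start", "end")
    ]
    per_gene_counts: dict[str, dict[str, float]] = {}
    per_gene_length: dict[str, int] = {}
    for row in exon_counts.itertuples(index=False):
        gene = row.gene_id
        exon_key = (row.contig, int(row.start), int(row.end))
        if gene not in known or exon_key not in known[gene]:
            raise KeyError(f"exon {exon_key} not annotated for gene {gene!r}")
        internal = exon_key in circle_internal_exons
        counts = per_gene_counts.setdefault(gene, {s: 0.0 for s in sample_cols})
        length = per_gene_length.setdefault(gene, 0)
        if internal:
            if not exclude_internal_length:
                per_gene_length[gene] = length + (exon_key[2] - exon_key[1])
            continue
        per_gene_length[gene] = length + (exon_key[2] - exon_key[1])
        for s in sample_cols:
            counts[s] += getattr(row, s)

    out = {g: HostGeneExpression(g) for g in per_gene_counts}
    for g, length in per_gene_length.items():
        if length == 0:
            warnings.warn(
                f"gene {g!r}: every exon is circle-internal; TPM set to 0", stacklevel=2
            )
    for s in sample_cols:
        rates = {}
        for g in per_gene_counts:
            length_kb = per_gene_length[g] / 1000.0
            rates[g] = per_gene_counts[g][s] / length_kb if length_kb > 0 else 0.0
        total = sum(rates.values())
        for g in per_gene_counts:
            out[g].counts[s] = int(per_gene_counts[g][s])
            out[g].tpm[s] = rates[g] / total * 1e6 if total > 0 else 0.0
    return out
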