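"""Candidate harmonization and the circRNA filter cascade.

Multi-source candidates (an independent chimeric-alignment detector plus
interop readers for external callers) are unioned by exact junction
coordinates, then filtered: genomic span, splice-site motif pairing,
multi-gene spanning, and minimum distinct-read support. The per-rule
rejection tally is reported in application order so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CircCandidate,
    CircRecord,
    MotifClass,
    Strand,
    TranscriptModel,
    sort_candidates,
)

__all__ = [
    "FilterConfig",
    "FilterResult",
    "harmonize",
    "apply_filters",
    "high_confidence_subset",
]

RULE_ORDER = ("span", "motif", "multi_gene", "support")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    ``max_span_nt`` is inclusive: spans up to and including the limit
    pass. ``min_distinct_reads`` distinct (coordinate-deduplicated)
    back-splice reads must be present in at least
    ``min_samples_with_min_reads`` samples.
    """

    max_span_nt: int = 100_000
    allowed_motifs: frozenset[MotifClass] = frozenset({MotifClass.GT_AG, MotifClass.GC_AG})
    min_distinct_reads: int = 2
    min_samples_with_min_reads: int = 1
    exclude_multi_gene: bool = True

    def __post_init__(self):
        if self.max_span_nt <= 0:
            raise ValueError("max_span_nt must be positive")
        if self.min_distinct_reads < 1:
            raise ValueError("min_distinct_reads must be >= 1")


@dataclass
class HarmonizeResult:
    candidates: list[CircCandidate]
    near_duplicates: list[tuple[CircCandidate, CircCandidate]] = field(default_factory=list)


def harmonize(*candidate_sets, near_duplicate_nt: int = 2) -> HarmonizeResult:
    """Union candidate sets by exact (contig, start, end, strand) identity.

    Provenance sets are merged and per-source reported counts retained
    side by side; authoritative counts come later from recounting.
    Distinct candidates whose boundaries differ by at most
    ``near_duplicate_nt`` on either side are flagged as near-duplicates in
    the diagnostics, but both are kept (exact-match rule).
    """
    merged: dict[tuple, CircCandidate] = {}
    for cand_set in candidate_sets:
        for cand in cand_set:
            prev = merged.get(cand.key)
            if prev is None:
                merged[cand.key] = cand
            else:
                merged[cand.key] = CircCandidate(
                    contig=cand.contig,
                    start=cand.start,
                    end=cand.end,
                    strand=cand.strand,
                    provenance=prev.provenance | cand.provenance,
                    reported_counts=prev.reported_counts + cand.reported_counts,
                )
    candidates = sort_candidates(merged.values())
    near = []
    by_contig: dict[tuple[str, Strand], list[CircCandidate]] = {}
    for c in candidates:
        by_contig.setdefault((c.contig, c.strand), []).append(c)
    for group in by_contig.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.start - a.start > near_duplicate_nt:
                    break
                if abs(a.start - b.start) <= near_duplicate_nt and abs(a.end - b.end) <= near_duplicate_nt:
                    near.append((a, b))
    return HarmonizeResult(candidates=candidates, near_duplicates=near)


@dataclass
class FilterResult:
    retained: list[CircRecord]
    rejected: dict[str, list[CircRecord]]

    @property
    def tally(self) -> dict[str, int]:
        return {rule: len(records) for rule, records in self.rejected.items()}

    @property
    def n_input(self) -> int:
        return len(self.retained) + sum(len(v) for v in self.rejected.values())


def _gene_extents(gene_models: list[TranscriptModel]) -> dict[str, tuple[str, int, int]]:
    extents: dict[str, tuple[str, int, int]] = {}
    for m in gene_models:
        prev = extents.get(m.gene_id)
        if prev is None:
            extents[m.gene_id] = (m.contig, m.genomic_start, m.genomic_end)
        else:
            extents[m.gene_id] = (
                prev[0], min(prev[1], m.genomic_start), max(prev[2], m.genomic_end)
            )
    return extents


def spans_disjoint_genes(
    contig: str, start: int, end: int, gene_models: list[TranscriptModel]
) -> bool:
    """True iff the span overlaps >= 2 genes that are themselves disjoint.

    Candidates overlapping several mutually overlapping genes are kept
    here (they are labeled ambiguous at annotation time).
    """
    hits = [
        (gs, ge)
        for gc, gs, ge in _gene_extents(gene_models).values()
        if gc == contig and gs < end and ge > start
    ]
    for i, (s1, e1) in enumerate(hits):
        for s2, e2 in hits[i + 1 :]:
            if e1 <= s2 or e2 <= s1:
                return True
    return False


def apply_filters(
    records: list[CircRecord],
    gene_models: list[TranscriptModel],
    config: FilterConfig | None = None,
) -> FilterResult:
    """Apply the filter cascade to quantified candidates.

    Each record must carry a classified motif and per-sample distinct-read
    counts (from the quantification step). A record is rejected by the
    first failing rule, in the fixed order span -> motif -> multi-gene ->
    support, so retained + per-rule rejections partition the input.
    """
    if config is None:
        config = FilterConfig()
    rejected: dict[str, list[CircRecord]] = {rule: [] for rule in RULE_ORDER}
    retained = []
    for rec in records:
        j = rec.junction
        if j.motif_class is None or not rec.distinct_reads and not rec.all_reads:
            raise ValueError(
                f"candidate {j.name} lacks motif/support information; quantify first"
            )
        if j.span > config.max_span_nt:
            rejected["span"].append(rec)
        elif j.motif_class not in config.allowed_motifs:
            rejected["motif"].append(rec)
        elif config.exclude_multi_gene and spans_disjoint_genes(
            j.contig, j.start, j.end, gene_models
        ):
            rejected["multi_gene"].append(rec)
        elif (
            sum(
                1
                for n in rec.distinct_reads.values()
                if n >= config.min_distinct_reads
            )
            < config.min_samples_with_min_reads
        ):
            rejected["support"].append(rec)
        else:
            retained.append(rec)
    return FilterResult(retained=sort_candidates(retained), rejected=rejected)


def high_confidence_subset(
    catalog: list[CircRecord], min_reads: int = 5, min_samples: int = 2
) -> list[CircRecord]:
    """Records with >= min_reads back-splice reads (duplicates included)
    in at least min_samples samples."""
    n_samples = len({s for r in catalog for s in r.all_reads})
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {n_samples} available samples"
        )
    return [
        r
        for r in catalog
        if sum(1 for n in r.all_reads.values() if n >= min_reads) >= min_samples
    ]
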