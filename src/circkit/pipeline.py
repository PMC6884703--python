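"""End-to-end orchestration: detect, harmonize, recount, filter, quantify.

This is the programmatic equivalent of running the CLI stages in
sequence; each step is the corresponding module function, so the pieces
remain individually testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    BackspliceJunction,
    ChimericRecord,
    CircCandidate,
    CircRecord,
    GenomeSequence,
    LinearJunctionRecord,
    MotifClass,
    SampleLibrary,
    TranscriptModel,
)
from .detect import CallStats, annotate_splice_status, call_junctions, classify_motif
from .filters import FilterConfig, FilterResult, apply_filters, harmonize
from .quantify import attach_metrics, count_backsplice

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    catalog: list[CircRecord]  # retained, quantified, metrics attached
    filter_result: FilterResult
    call_stats: CallStats
    near_duplicates: list = field(default_factory=list)


def run_pipeline(
    chimeric_records: list[ChimericRecord],
    linear_records: list[LinearJunctionRecord],
    genome: GenomeSequence,
    transcript_models: list[TranscriptModel],
    libraries: list[SampleLibrary],
    caller_candidate_sets: list[list[CircCandidate]] = (),
    min_overhang: int = 15,
    filter_config: FilterConfig | None = None,
) -> PipelineResult:
    """Run the full consolidated pipeline on junction evidence.

    Candidates from the native chimeric-alignment detector are unioned
    with any external caller candidates, support is recounted from the
    chimeric records with coordinate-based duplicate flagging, the filter
    cascade is applied, and abundance metrics (RPM, linear support, CLR,
    percent circularized) are attached to the retained catalog.
    """
    stats = CallStats()
    native = call_junctions(chimeric_records, min_overhang=min_overhang, stats=stats)
    native_candidates = [
        CircCandidate(j.contig, j.start, j.end, j.strand, provenance=frozenset({"native"}))
        for j in native
    ]
    harmonized = harmonize(native_candidates, *caller_candidate_sets)

    junctions = []
    provenance = {}
    for cand in harmonized.candidates:
        junction = BackspliceJunction(cand.contig, cand.start, cand.end, cand.strand)
        try:
            motif = classify_motif(junction, genome)
        except (IndexError, KeyError):
            motif = MotifClass.OTHER  # unplaceable boundary cannot be canonical
        junction = annotate_splice_status(
            BackspliceJunction(cand.contig, cand.start, cand.end, cand.strand, motif_class=motif),
            transcript_models,
        )
        junctions.append(junction)
        provenance[junction.key] = cand.provenance

    counted = count_backsplice(junctions, chimeric_records, libraries, min_overhang=min_overhang)
    records = []
    for junction in junctions:
        rec = counted[junction.key]
        rec.provenance = provenance[junction.key]
        records.append(rec)

    result = apply_filters(records, transcript_models, filter_config)
    attach_metrics(result.retained, libraries, linear_records)
    return PipelineResult(
        catalog=result.retained,
        filter_result=result,
        call_stats=stats,
        near_duplicates=harmonized.near_duplicates,
    )
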