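"""Genomic annotation of circRNAs against transcript models.

Assigns a best parental transcript whose annotated splice sites coincide
with the back-splice boundaries, infers the putative internal exon
structure (conservatively, all parental exons between the boundaries),
classifies the genomic origin of each boundary, and derives exon-rank
spectra, alternative back-splicing summaries and length features.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .core import (
    BackspliceJunction,
    CircAnnotation,
    CircRecord,
    Strand,
    TranscriptModel,
)

__all__ = [
    "assign_parental_transcript",
    "classify_origin",
    "exon_rank_spectrum",
    "alt_backsplice_summary",
    "length_features",
    "annotate_catalog",
    "AltBacksplicingSummary",
]


def _boundary_match(junction: BackspliceJunction, model: TranscriptModel) -> tuple[int | None, int | None]:
    """(acceptor_rank, donor_rank) of exons whose boundaries coincide.

    The acceptor boundary must coincide with an exon's transcript-
    orientation start, the donor boundary with an exon's end.
    """
    acceptor_rank = donor_rank = None
    for exon in model.exons:
        if model.strand is Strand.PLUS:
            tx_start, tx_end = exon.start, exon.end  # genomic == transcript order
            if tx_start == junction.start:
                acceptor_rank = exon.rank
            if tx_end == junction.end:
                donor_rank = exon.rank
        else:
            if exon.end == junction.end:
                acceptor_rank = exon.rank
            if exon.start == junction.start:
                donor_rank = exon.rank
    return acceptor_rank, donor_rank


def _gene_extents(models: list[TranscriptModel]) -> dict[str, tuple[str, int, int]]:
    extents: dict[str, tuple[str, int, int]] = {}
    for m in models:
        prev = extents.get(m.gene_id)
        if prev is None:
            extents[m.gene_id] = (m.contig, m.genomic_start, m.genomic_end)
        else:
            extents[m.gene_id] = (prev[0], min(prev[1], m.genomic_start), max(prev[2], m.genomic_end))
    return extents


def assign_parental_transcript(
    junction: BackspliceJunction, transcript_models: list[TranscriptModel]
) -> CircAnnotation:
    """Choose a best parental transcript and infer the internal structure.

    Both-sides matches are preferred over single-side matches; within a
    tier, canonical transcripts win, then longer CDS, then lexicographic
    transcript id (a deterministic tie-break). Spans overlapping more
    than one gene are labeled ambiguous when the genes themselves overlap
    and multi_gene when they are disjoint; spans with no overlapping exon
    are intronic inside a gene and intergenic outside.
    """
    overlapping_genes = {
        g: ext
        for g, ext in _gene_extents(transcript_models).items()
        if ext[0] == junction.contig and ext[1] < junction.end and ext[2] > junction.start
    }
    if len(overlapping_genes) > 1:
        items = list(overlapping_genes.values())
        disjoint = any(
            e1 <= s2 or e2 <= s1
            for i, (_, s1, e1) in enumerate(items)
            for (_, s2, e2) in items[i + 1 :]
        )
        return CircAnnotation(
            origin_class="multi_gene" if disjoint else "ambiguous",
            genomic_span=junction.span,
        )

    candidates = [
        m
        for m in transcript_models
        if m.contig == junction.contig
        and m.strand == junction.strand
        and m.genomic_start < junction.end
        and m.genomic_end > junction.start
    ]
    scored = []
    for m in candidates:
        acc_rank, don_rank = _boundary_match(junction, m)
        n_matched = (acc_rank is not None) + (don_rank is not None)
        scored.append((n_matched, m, acc_rank, don_rank))
    scored.sort(
        key=lambda t: (
            -(t[0] == 2),
            not t[1].canonical_flag,
            -t[0],
            -t[1].cds_length,
            t[1].transcript_id,
        )
    )

    if scored and scored[0][0] > 0:
        n_matched, model, acc_rank, don_rank = scored[0]
        internal = [
            e
            for e in model.exons
            if e.start >= junction.start and e.end <= junction.end
        ]
        annotation = CircAnnotation(
            origin_class="",  # refined by classify_origin
            parental_transcript_id=model.transcript_id,
            gene_id=model.gene_id,
            gene_name=model.gene_name,
            internal_exons=internal,
            acceptor_exon_rank=acc_rank,
            donor_exon_rank=don_rank,
            spliced_length=sum(e.length for e in internal),
            genomic_span=junction.span,
        )
        return classify_origin(annotation, junction, model)

    # No splice-site match: exonic overlap still places the circle in a
    # gene; otherwise it is intronic (inside a gene) or intergenic.
    exon_overlap = any(
        e.start < junction.end and e.end > junction.start
        for m in candidates
        for e in m.exons
    )
    if exon_overlap:
        model = scored[0][1] if scored else candidates[0]
        annotation = CircAnnotation(
            origin_class="",
            parental_transcript_id=None,
            gene_id=model.gene_id,
            gene_name=model.gene_name,
            genomic_span=junction.span,
        )
        return classify_origin(annotation, junction, model)
    if overlapping_genes:
        gene_id = next(iter(overlapping_genes))
        return CircAnnotation(
            origin_class="intronic", gene_id=gene_id, genomic_span=junction.span
        )
    return CircAnnotation(origin_class="intergenic", genomic_span=junction.span)


def _region_of(position: int, model: TranscriptModel) -> str:
    """Region label of a genomic base within a transcript.

    CDS / UTR5 / UTR3 by containment, with transcript orientation
    deciding which UTR; exonic bases of non-coding transcripts are
    ``exonic_noncoding``; bases outside exons are ``intron``.
    """
    in_exon = any(e.start <= position < e.end for e in model.exons)
    if not in_exon:
        return "intron"
    if not model.cds_intervals:
        return "exonic_noncoding"
    if any(s <= position < e for s, e in model.cds_intervals):
        return "CDS"
    cds_start = min(s for s, _ in model.cds_intervals)
    cds_end = max(e for _, e in model.cds_intervals)
    if position < cds_start:
        return "UTR5" if model.strand is Strand.PLUS else "UTR3"
    if position >= cds_end:
        return "UTR3" if model.strand is Strand.PLUS else "UTR5"
    return "intron"  # between CDS pieces but outside exons cannot happen here


def classify_origin(
    annotation: CircAnnotation,
    junction: BackspliceJunction,
    model: TranscriptModel,
) -> CircAnnotation:
    """Label each boundary's transcript region and the overall origin.

    The boundary positions are the first exonic base on the acceptor side
    and the last exonic base on the donor side. The overall class is CDS
    when both boundaries are coding, a UTR class when either boundary
    falls in a UTR (5' wins over 3' in mixed cases), exonic_noncoding for
    non-coding exons, and intronic when neither boundary is exonic.
    """
    if junction.strand is Strand.PLUS:
        acceptor_pos, donor_pos = junction.start, junction.end - 1
    else:
        acceptor_pos, donor_pos = junction.end - 1, junction.start
    acceptor_region = _region_of(acceptor_pos, model)
    donor_region = _region_of(donor_pos, model)
    regions = {acceptor_region, donor_region}
    if regions == {"CDS"}:
        overall = "CDS"
    elif "UTR5" in regions:
        overall = "UTR5"
    elif "UTR3" in regions:
        overall = "UTR3"
    elif "CDS" in regions:
        overall = "CDS"
    elif "exonic_noncoding" in regions:
        overall = "exonic_noncoding"
    else:
        overall = "intronic"
    annotation.acceptor_region = acceptor_region
    annotation.donor_region = donor_region
    annotation.origin_class = overall
    return annotation


def exon_rank_spectrum(
    annotations: list[CircAnnotation], transcript_models: list[TranscriptModel]
) -> dict[str, dict[int, float]]:
    """Normalized exon-rank frequency for acceptor and donor sites.

    For rank r the normalized frequency is (number of circRNAs using an
    exon of rank r on that side) / (number of genes with at least r+1
    exons). Ranks whose denominator is zero are omitted with a warning.
    Only annotations with a parental transcript and both ranks defined
    contribute.
    """
    import warnings

    gene_exon_counts: dict[str, int] = {}
    for m in transcript_models:
        gene_exon_counts[m.gene_id] = max(gene_exon_counts.get(m.gene_id, 0), m.n_exons)
    n_genes_with_at_least = Counter()
    for n in gene_exon_counts.values():
        for r in range(1, n + 1):
            n_genes_with_at_least[r] += 1

    spectra: dict[str, dict[int, float]] = {"acceptor": {}, "donor": {}}
    usable = [
        a
        for a in annotations
        if a.parental_transcript_id is not None
        and a.acceptor_exon_rank is not None
        and a.donor_exon_rank is not None
    ]
    for side, rank_attr in (("acceptor", "acceptor_exon_rank"), ("donor", "donor_exon_rank")):
        counts = Counter(getattr(a, rank_attr) for a in usable)
        for rank, count in sorted(counts.items()):
            denom = n_genes_with_at_least.get(rank + 1, 0)
            if denom == 0:
                warnings.warn(
                    f"rank {rank}: no gene has >= {rank + 1} exons; rank omitted",
                    stacklevel=2,
                )
                continue
            spectra[side][rank] = count / denom
    return spectra


@dataclass
class AltBacksplicingSummary:
    isoforms_per_gene: dict[str, int]
    alternative_sites: dict[tuple, bool]  # (contig, strand, position, side) -> is alternative
    fraction_alternative_donor: float = 0.0
    fraction_alternative_acceptor: float = 0.0
    site_partner_counts: dict[tuple, int] = field(default_factory=dict)


def alt_backsplice_summary(catalog: list[CircRecord]) -> AltBacksplicingSummary:
    """Per-gene isoform counts and per-site alternative-use flags.

    A back-splice site (boundary) is alternative when it pairs with more
    than one partner site across distinct junctions. Records without a
    host gene are grouped under their own junction name.
    """
    per_gene: Counter = Counter()
    partners: dict[tuple, set[int]] = {}
    for rec in catalog:
        j = rec.junction
        gene = rec.annotation.gene_id if rec.annotation and rec.annotation.gene_id else j.name
        per_gene[gene] += 1
        acc_site = (j.contig, j.strand.value, j.acceptor_boundary, "acceptor")
        don_site = (j.contig, j.strand.value, j.donor_boundary, "donor")
        partners.setdefault(acc_site, set()).add(j.donor_boundary)
        partners.setdefault(don_site, set()).add(j.acceptor_boundary)
    alternative = {site: len(p) > 1 for site, p in partners.items()}
    donor_sites = [s for s in alternative if s[3] == "donor"]
    acceptor_sites = [s for s in alternative if s[3] == "acceptor"]
    return AltBacksplicingSummary(
        isoforms_per_gene=dict(per_gene),
        alternative_sites=alternative,
        fraction_alternative_donor=(
            sum(alternative[s] for s in donor_sites) / len(donor_sites) if donor_sites else 0.0
        ),
        fraction_alternative_acceptor=(
            sum(alternative[s] for s in acceptor_sites) / len(acceptor_sites)
            if acceptor_sites
            else 0.0
        ),
        site_partner_counts={s: len(p) for s, p in partners.items()},
    )


def length_features(
    annotation: CircAnnotation,
    junction: BackspliceJunction,
    transcript_models: list[TranscriptModel],
) -> CircAnnotation:
    """Fill flanking intron lengths, spliced length, and genomic span.

    The upstream flanking intron precedes the acceptor exon and the
    downstream intron follows the donor exon, both in transcript
    orientation; at terminal exons the corresponding length is None.
    """
    annotation.genomic_span = junction.span
    if annotation.parental_transcript_id is None:
        return annotation
    model = next(
        m for m in transcript_models if m.transcript_id == annotation.parental_transcript_id
    )
    introns = model.introns()  # transcript orientation, intron i sits after exon rank i
    acc_rank, don_rank = annotation.acceptor_exon_rank, annotation.donor_exon_rank
    if acc_rank is not None and acc_rank >= 2:
        s, e = introns[acc_rank - 2]
        annotation.upstream_intron_length = e - s
    else:
        annotation.upstream_intron_length = None
    if don_rank is not None and don_rank <= len(introns):
        s, e = introns[don_rank - 1]
        annotation.downstream_intron_length = e - s
    else:
        annotation.downstream_intron_length = None
    if annotation.internal_exons:
        annotation.spliced_length = sum(e.length for e in annotation.internal_exons)
    return annotation


def annotate_catalog(
    catalog: list[CircRecord], transcript_models: list[TranscriptModel]
) -> list[CircRecord]:
    """Attach a full annotation (parental transcript, origin, lengths)."""
    for rec in catalog:
        annotation = assign_parental_transcript(rec.junction, transcript_models)
        rec.annotation = length_features(annotation, rec.junction, transcript_models)
    return catalog
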