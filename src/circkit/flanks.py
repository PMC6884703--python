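"""Flanking-intron analyses: repeat pairs, inverted complementarity, and
signal metaprofiles around back-splice sites.

Complementary sequences in the introns flanking the back-splice sites
(classically inverted Alu retrotransposon pairs) can bring the two sites
into proximity and promote circularization. These analyses take a fixed
window of intronic sequence immediately outside each boundary and ask (a)
whether family repeats sit in both windows and in which relative
orientation, and (b) whether the windows contain an extended complementary
stretch, detected as a Smith-Waterman local alignment of the upstream
window against the reverse complement of the downstream window.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .core import (
    BackspliceJunction,
    CrosslinkSite,
    GenomeSequence,
    RepeatFeature,
    Strand,
    reverse_complement,
)

__all__ = [
    "RepeatPairResult",
    "repeat_pair_orientation",
    "LocalAlignmentResult",
    "inverted_complementarity",
    "merge_crosslink_sites",
    "MergedCluster",
    "MetaProfile",
    "signal_metaprofile",
]


@dataclass(frozen=True)
class RepeatPairResult:
    upstream_has_repeat: bool
    downstream_has_repeat: bool
    orientation: str  # inverted / same / none


def repeat_pair_orientation(
    junction: BackspliceJunction,
    repeats: list[RepeatFeature],
    window: int = 500,
    family: str | None = "Alu",
) -> RepeatPairResult:
    """Repeat presence in the two flanking windows and pair orientation.

    Windows are the ``window`` intronic nucleotides immediately outside
    each boundary (genomic left of start, genomic right of end). Over all
    cross-window repeat pairs: any opposite-strand pair -> inverted;
    pairs existing and all same-strand -> same; either window empty ->
    none.
    """
    if family is not None:
        repeats = [
            r for r in repeats if family in r.repeat_family or family in r.repeat_name
        ]
    left_win = (max(junction.start - window, 0), junction.start)
    right_win = (junction.end, junction.end + window)
    left = [
        r
        for r in repeats
        if r.contig == junction.contig and r.start < left_win[1] and r.end > left_win[0]
    ]
    right = [
        r
        for r in repeats
        if r.contig == junction.contig and r.start < right_win[1] and r.end > right_win[0]
    ]
    if not left or not right:
        orientation = "none"
    elif any(a.strand != b.strand for a in left for b in right):
        orientation = "inverted"
    else:
        orientation = "same"
    return RepeatPairResult(
        upstream_has_repeat=bool(left),
        downstream_has_repeat=bool(right),
        orientation=orientation,
    )


@dataclass(frozen=True)
class LocalAlignmentResult:
    length: int  # alignment columns (matches + mismatches + internal gaps)
    percent_identity: float
    score: float
    upstream_interval: tuple[int, int]  # within the upstream window
    downstream_interval: tuple[int, int]  # within the reverse-complemented downstream window
    complementary: bool


def inverted_complementarity(
    junction: BackspliceJunction,
    genome: GenomeSequence,
    window: int = 500,
    gap_open: float = 10.0,
    gap_extend: float = 4.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    min_identity: float = 85.0,
    min_length: int = 40,
) -> LocalAlignmentResult | None:
    """Best local alignment between the flanking windows in inverted
    orientation.

    The upstream window is aligned against the reverse complement of the
    downstream window with affine gap penalties. The junction is flagged
    complementary when the best alignment reaches both the identity and
    length thresholds. Windows are truncated at contig boundaries;
    windows shorter than 10 nt leave the result undefined (None).
    """
    upstream = genome.fetch_truncated(junction.contig, junction.start - window, junction.start)
    downstream = genome.fetch_truncated(junction.contig, junction.end, junction.end + window)
    if len(upstream) < 10 or len(downstream) < 10:
        return None
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=-abs(gap_open),
        extend_gap_score=-abs(gap_extend),
    )
    alignments = aligner.align(upstream, reverse_complement(downstream))
    if len(alignments) == 0:
        return LocalAlignmentResult(0, 0.0, 0.0, (0, 0), (0, 0), False)
    best = alignments[0]
    counts = best.counts()
    length = counts.identities + counts.mismatches + counts.internal_gaps
    identity = 100.0 * counts.identities / length if length else 0.0
    tgt = best.aligned[0]
    qry = best.aligned[1]
    upstream_iv = (int(tgt[0][0]), int(tgt[-1][1])) if len(tgt) else (0, 0)
    downstream_iv = (int(qry[0][0]), int(qry[-1][1])) if len(qry) else (0, 0)
    return LocalAlignmentResult(
        length=int(length),
        percent_identity=identity,
        score=float(best.score),
        upstream_interval=upstream_iv,
        downstream_interval=downstream_iv,
        complementary=identity >= min_identity and length >= min_length,
    )


@dataclass(frozen=True)
class MergedCluster:
    contig: str
    start: int  # position of the first site
    end: int  # position of the last site (inclusive span of single-nt sites)
    strand: Strand
    n_sites: int
    total_count: int


def merge_crosslink_sites(
    sites: list[CrosslinkSite], max_gap: int = 8
) -> list[MergedCluster]:
    """Merge single-nucleotide crosslink sites within ``max_gap`` nt.

    Same-contig, same-strand sites whose successive positional distance
    is <= max_gap join one cluster transitively. Idempotent and
    order-independent: input order does not matter and re-merging cluster
    anchor positions yields the same clusters.
    """
    clusters: list[MergedCluster] = []
    by_group: dict[tuple[str, Strand], list[CrosslinkSite]] = {}
    for s in sites:
        by_group.setdefault((s.contig, s.strand), []).append(s)
    for (contig, strand), group in sorted(by_group.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        group = sorted(group, key=lambda s: s.position)
        current: list[CrosslinkSite] = []
        for site in group:
            if current and site.position - current[-1].position <= max_gap:
                current.append(site)
            else:
                if current:
                    clusters.append(_make_cluster(contig, strand, current))
                current = [site]
        if current:
            clusters.append(_make_cluster(contig, strand, current))
    return clusters


def _make_cluster(contig: str, strand: Strand, sites: list[CrosslinkSite]) -> MergedCluster:
    return MergedCluster(
        contig=contig,
        start=sites[0].position,
        end=sites[-1].position,
        strand=strand,
        n_sites=len(sites),
        total_count=sum(s.count for s in sites),
    )


@dataclass
class MetaProfile:
    """Mean signal per relative position on each side of the junctions.

    Offsets run from -intron_window (deep in the flanking intron) to -1
    (the base immediately outside the boundary), then +1 to +exon_window
    (into the circularized exon), in transcript orientation. The acceptor
    side is the 3' back-splice site, the donor side the 5' site.
    """

    offsets: list[int]
    acceptor: list[float]
    donor: list[float]
    n_junctions: int

    def total_signal(self) -> float:
        return (sum(self.acceptor) + sum(self.donor)) * self.n_junctions


def signal_metaprofile(
    junctions: list[BackspliceJunction],
    sites: list[CrosslinkSite],
    intron_window: int = 250,
    exon_window: int = 50,
) -> MetaProfile:
    """Average per-position signal around the two back-splice sites.

    For each junction and side, genomic positions are mapped to relative
    offsets in transcript orientation; the profile holds the mean count
    across junctions at each offset. Positions beyond contig ends simply
    contribute zero while the junction still counts toward the mean, so
    sum(mean per position) * n_junctions equals the total overlapped
    signal exactly on integer inputs.
    """
    if not junctions:
        raise ValueError("empty junction set")
    signal: dict[tuple[str, Strand, int], int] = {}
    for s in sites:
        key = (s.contig, s.strand, s.position)
        signal[key] = signal.get(key, 0) + s.count

    offsets = list(range(-intron_window, 0)) + list(range(1, exon_window + 1))
    acc_total = [0.0] * len(offsets)
    don_total = [0.0] * len(offsets)
    for j in junctions:
        for i, off in enumerate(offsets):
            acc_total[i] += signal.get((j.contig, j.strand, _acceptor_pos(j, off)), 0)
            don_total[i] += signal.get((j.contig, j.strand, _donor_pos(j, off)), 0)
    n = len(junctions)
    return MetaProfile(
        offsets=offsets,
        acceptor=[v / n for v in acc_total],
        donor=[v / n for v in don_total],
        n_junctions=n,
    )


def _acceptor_pos(j: BackspliceJunction, off: int) -> int:
    """Genomic position at transcript-orientation offset from the acceptor
    boundary: negative offsets are intronic (upstream), positive exonic."""
    if j.strand is Strand.PLUS:
        # acceptor boundary at start; intron to the left, exon to the right
        return j.start + off if off < 0 else j.start + off - 1
    # minus strand: acceptor boundary at end; intron to the right
    return j.end - 1 - off if off < 0 else j.end - off


def _donor_pos(j: BackspliceJunction, off: int) -> int:
    """Same axis for the donor boundary: negative offsets intronic
    (downstream of the circle), positive exonic (inside the circle)."""
    if j.strand is Strand.PLUS:
        # donor boundary at end; exon to the left, intron to the right
        return j.end - off - 1 if off < 0 else j.end - off
    return j.start + off if off < 0 else j.start + off - 1
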