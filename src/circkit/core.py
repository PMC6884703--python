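"""Core domain types shared across the toolkit.

All genomic intervals use 0-based half-open coordinates with an explicit
strand. The external dialects this package reads (STAR junction tables,
GTF, BED variants, RepeatMasker tracks) disagree on conventions; every
reader normalizes on input and every writer documents the convention in
its header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Strand",
    "MotifClass",
    "SpliceStatus",
    "GenomeSequence",
    "ChimericRecord",
    "LinearJunctionRecord",
    "CircCandidate",
    "RepeatFeature",
    "BackspliceJunction",
    "ExonInterval",
    "TranscriptModel",
    "CircAnnotation",
    "SampleLibrary",
    "CircRecord",
    "CrosslinkSite",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, symbol: str) -> "Strand":
        symbol = {"0": ".", "1": "+", "2": "-", "−": "-"}.get(symbol, symbol)
        try:
            return cls(symbol)
        except ValueError:
            raise ValueError(f"unknown strand symbol {symbol!r}") from None

    def flip(self) -> "Strand":
        if self is Strand.PLUS:
            return Strand.MINUS
        if self is Strand.MINUS:
            return Strand.PLUS
        return self


class MotifClass(str, Enum):
    """Splice-site dinucleotide pairing at a back-splice junction.

    GT_AG is the canonical donor/acceptor pair (GU/AG on the RNA), GC_AG
    the accepted minor class; everything else, including motifs containing
    N, is OTHER.
    """

    GT_AG = "GT_AG"
    GC_AG = "GC_AG"
    OTHER = "other"


class SpliceStatus(str, Enum):
    ANNOTATED = "annotated"
    DE_NOVO = "de_novo"


class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string.

    Lookup is by 0-based half-open interval and is strict: requesting bases
    outside a contig raises instead of clamping, so coordinate bugs surface
    immediately.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, contig: str) -> int:
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        try:
            seq = self._contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"interval {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def fetch_truncated(self, contig: str, start: int, end: int) -> str:
        """Like :meth:`fetch` but silently truncates at contig boundaries."""
        seq = self._contigs[contig]
        return seq[max(start, 0) : min(end, len(seq))]

    def items(self):
        return self._contigs.items()


@dataclass(frozen=True)
class ChimericRecord:
    """One read's two-segment discontinuous alignment.

    ``donor_site`` is the 0-based position of the first intronic base 3' of
    the donor exon; ``acceptor_site`` the 0-based intronic base adjacent to
    the acceptor exon. Both are converted from the aligner's 1-based
    columns on input.
    """

    read_id: str
    contig: str
    strand: Strand
    donor_site: int
    acceptor_site: int
    junction_motif_code: int
    seg1_pos: int
    seg1_cigar: str
    seg2_pos: int
    seg2_cigar: str
    sample_id: str
    acceptor_contig: str | None = None

    @property
    def cross_contig(self) -> bool:
        return self.acceptor_contig is not None and self.acceptor_contig != self.contig

    @property
    def duplicate_key(self) -> tuple:
        return (
            self.contig,
            self.strand,
            self.seg1_pos,
            self.seg1_cigar,
            self.seg2_pos,
            self.seg2_cigar,
        )


@dataclass(frozen=True)
class LinearJunctionRecord:
    contig: str
    intron_start: int
    intron_end: int
    strand: Strand
    unique_reads: int
    multi_reads: int
    annotated_flag: bool
    sample_id: str

    def __post_init__(self):
        if self.intron_start >= self.intron_end:
            raise ValueError("intron_start must be < intron_end")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class CircCandidate:
    contig: str
    start: int
    end: int
    strand: Strand
    provenance: frozenset[str] = frozenset()
    reported_counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid candidate span {self.start}-{self.end}")
        if self.strand not in (Strand.PLUS, Strand.MINUS):
            raise ValueError("candidate strand must be + or -")

    @property
    def key(self) -> tuple[str, int, int, Strand]:
        return (self.contig, self.start, self.end, self.strand)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatFeature:
    contig: str
    start: int
    end: int
    strand: Strand
    repeat_name: str
    repeat_family: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("repeat start must be < end")


@dataclass(frozen=True)
class BackspliceJunction:
    """Strand-aware circularized genomic span.

    ``start`` is the 0-based inclusive left boundary of the circularized
    region, ``end`` the exclusive right boundary. On the + strand the
    acceptor exon begins at ``start`` and the donor exon ends at ``end``;
    on the - strand the roles of the two boundaries swap.
    """

    contig: str
    start: int
    end: int
    strand: Strand
    motif_class: MotifClass | None = None
    acceptor_status: SpliceStatus | None = None
    donor_status: SpliceStatus | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("junction start must be < end")

    @property
    def key(self) -> tuple[str, int, int, Strand]:
        return (self.contig, self.start, self.end, self.strand)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand.value})"

    @property
    def acceptor_boundary(self) -> int:
        """Genomic coordinate of the acceptor-side splice boundary."""
        return self.start if self.strand is Strand.PLUS else self.end

    @property
    def donor_boundary(self) -> int:
        return self.end if self.strand is Strand.PLUS else self.start


@dataclass(frozen=True)
class ExonInterval:
    contig: str
    start: int
    end: int
    rank: int  # 1-based in transcript orientation

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("exon start must be < end")
        if self.rank < 1:
            raise ValueError("exon rank is 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: Strand
    exons: list[ExonInterval]
    canonical_flag: bool = False
    support_level: int | None = None
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        # Exons stored 5'->3' in transcript orientation; genomic order is
        # ascending on + and descending on -.
        ordered = sorted(self.exons, key=lambda e: e.start, reverse=self.strand is Strand.MINUS)
        self.exons = [replace(e, rank=i + 1) for i, e in enumerate(ordered)]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def genomic_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals ordered 5'->3' in transcript orientation."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand is Strand.MINUS:
                out.append((b.end, a.start))
            else:
                out.append((a.end, b.start))
        return out


@dataclass(frozen=True)
class SampleLibrary:
    sample_id: str
    condition: str
    library_size: int  # total mapped reads

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValueError("library size must be positive")


@dataclass
class CircAnnotation:
    origin_class: str  # CDS / UTR5 / UTR3 / exonic_noncoding / intronic / intergenic / ambiguous / multi_gene
    parental_transcript_id: str | None = None
    gene_id: str | None = None
    gene_name: str | None = None
    internal_exons: list[ExonInterval] = field(default_factory=list)
    acceptor_exon_rank: int | None = None
    donor_exon_rank: int | None = None
    acceptor_region: str | None = None
    donor_region: str | None = None
    upstream_intron_length: int | None = None
    downstream_intron_length: int | None = None
    spliced_length: int | None = None
    genomic_span: int | None = None


@dataclass
class CircRecord:
    """A back-splice junction with per-sample evidence and metrics."""

    junction: BackspliceJunction
    provenance: frozenset[str] = frozenset()
    all_reads: dict[str, int] = field(default_factory=dict)
    distinct_reads: dict[str, int] = field(default_factory=dict)
    linear_support: dict[str, float] = field(default_factory=dict)
    rpm: dict[str, float] = field(default_factory=dict)
    clr: dict[str, float] = field(default_factory=dict)
    percent_circularized: dict[str, float | None] = field(default_factory=dict)
    annotation: CircAnnotation | None = None

    def __post_init__(self):
        for s, d in self.distinct_reads.items():
            if d > self.all_reads.get(s, 0):
                raise ValueError(f"distinct > all reads for sample {s}")

    @property
    def key(self):
        return self.junction.key

    @property
    def name(self) -> str:
        return self.junction.name

    def total_all_reads(self) -> int:
        return sum(self.all_reads.values())

    def max_distinct(self) -> int:
        return max(self.distinct_reads.values(), default=0)


@dataclass(frozen=True)
class CrosslinkSite:
    contig: str
    position: int  # 0-based single-nucleotide position
    strand: Strand
    count: int = 1


def sort_candidates(items: Iterable) -> list:
    """Canonical (contig, start, end, strand) order for any keyed record."""
    return sorted(items, key=lambda x: (x.key[0], x.key[1], x.key[2], x.key[3].value))
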