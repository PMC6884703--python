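# Methods

This note documents the models, conventions and numerical choices behind
`circkit`, and what the synthetic benchmark does and does not show.

## Coordinate conventions and junction model

All genomic intervals are 0-based half-open with explicit strand. The
source dialects disagree — BED variants are 0-based, GTF and the
STAR-style junction/SJ tables 1-based — so every reader normalizes on
input and every writer documents its convention in a header line.

A back-splice junction is the circularized span `[start, end)`. On the
`+` strand the acceptor exon begins at `start` and the donor exon ends at
`end`; on the `-` strand the two roles swap. From a chimeric record whose
donor/acceptor columns give the first intronic base adjacent to each
exon, the mapping is `start = acceptor_site + 1, end = donor_site` on `+`
and `start = donor_site + 1, end = acceptor_site` on `-`. A record
qualifies only when both segments are on one contig and strand, the sites
are in head-to-tail order, and the shorter segment's aligned length
(M/=/X from its CIGAR) reaches the overhang minimum (default 15 nt,
matching the aligner settings used to produce such tables).

Splice-site motifs are read strand-aware from the template: on `+`,
donor dinucleotide at `[end, end+2)` and acceptor at `[start−2, start)`;
on `-`, both as reverse complements from the mirrored boundaries. Note
that a back-splice junction's genomic context is the *reversal* of a
linear intron's: `AG … GT` around the span on `+`, hence `AC … CT` on the
plus-strand sequence for a `-` junction. GT..AG and GC..AG are accepted;
anything else, including motifs containing N, is `other`.

## Harmonization and filtering

Candidates from the native detector and external caller files are
unioned by exact coordinates; provenance is the union and per-source
counts are kept for diagnostics only. Junction pairs differing by ≤ 2 nt
are reported as near-duplicates but never merged — the exact-match rule
keeps behavior predictable, and coordinate reconciliation between callers
with different conventions is the normalizing readers' job.

The filter cascade runs in a fixed, reported order (span → motif →
multi-gene → support) so rejection tallies are reproducible; a candidate
is charged to the first rule it fails. Choices:

* The span rule is inclusive (`end − start ≤ 100 000`, configurable).
* The multi-gene rule rejects only spans crossing two genes that are
  themselves disjoint in genomic extent; spans over mutually overlapping
  genes are kept and later labeled `ambiguous`.
* Presence uses *distinct* reads (coordinate-keyed duplicate flagging:
  contig, strand, both segment positions and CIGARs); abundance uses all
  reads. The default presence rule is ≥ 2 distinct reads in ≥ 1 sample;
  the high-confidence subset needs ≥ 5 reads (duplicates included) in
  ≥ 2 samples.
* Junctions whose same span is claimed on both strands by different
  records are dropped as alignment inconsistencies.

## Quantification

Support is always recounted from the chimeric records against the final
catalog, so estimates do not depend on which caller reported a junction.
Per sample: RPM = all reads / library size × 10⁶ (per-sample library
sizes, never pooled). Linear support is the mean over the two splice
sites of the summed unique linear-junction reads sharing that exact site;
alternative linear partners at one site are summed before averaging.
CLR = back / (linear + 1): the pseudocount stabilizes the denominator
only (an `all-sides` variant is available for sensitivity analysis).
Percent circularized = 100·back/(back+linear), undefined (None/NA) when
both are zero — deliberately distinct from 0 %, which means "linear only".
Both junction-level metrics ignore isoforms that skip the circularized
exons entirely and can overestimate relative circRNA abundance in such
genes.

Host-gene TPM excludes exons internal to a circRNA from the counts *and*
from the effective gene length (excluding only reads would bias the rate
downward); the exclusion of length is configurable. Genes whose every
exon is circle-internal get TPM 0 with a warning. Column sums are 10⁶ by
construction whenever any gene has nonzero counts.

## Annotation

Parental transcripts are chosen among same-strand transcripts overlapping
the span: transcripts matching both boundaries at annotated splice sites
outrank single-side matches; within a tier, canonical transcripts win,
then longer CDS, then lexicographic transcript id. The both-sides-first
ordering means a non-canonical transcript with coincident splice sites
beats a canonical transcript matching only one side — the tie-break is a
documented design choice, not an inference about any particular dataset.
Canonical status comes from a GTF tag containing "canonical" or a
user-supplied id list. Internal structure is conservative: every parental
exon between the boundaries is included; internal alternative splicing is
not modeled.

Origin classes: both boundaries coding → `CDS`; any boundary in a UTR →
`UTR5`/`UTR3` (5′ wins in mixed cases); exonic boundaries of non-coding
transcripts → `exonic_noncoding` (an addition to the usual class set —
collapsing these into CDS would be wrong); no exon overlap → `intronic`
inside a gene, `intergenic` outside; spans over >1 mutually overlapping
genes → `ambiguous`; over disjoint genes → `multi_gene` (normally removed
by the filter).

The exon-rank spectrum normalizes the count of circRNAs using rank *r*
(acceptor or donor side) by the number of genes with ≥ r+1 exons, so late
ranks are not penalized merely for being rare in the genome; a gene's
exon count is the maximum over its transcripts. Ranks with a zero
denominator are omitted with a warning.

## Flanking-sequence analysis

Repeat windows are the 500 intronic nucleotides immediately outside each
boundary (truncated at contig ends); overlap into neighboring exons is
not trimmed. Orientation is computed over *all* cross-window repeat
pairs: any opposite-strand pair ⇒ inverted (inverted dominates mixed
cases), otherwise same; either window empty ⇒ none.

Inverted complementarity aligns the upstream window against the reverse
complement of the downstream window with affine-gap Smith–Waterman
(match +1, mismatch −1, gap open 10, extend 4 — all exposed as
parameters). Alignment length counts matches + mismatches + internal
gaps; identity is matches/length × 100; the complementary flag uses
≥ 85 % identity and ≥ 40 nt, both configurable. Windows shorter than
10 nt after truncation give an undefined result.

Crosslink sites merge transitively at successive distances ≤ 8 nt within
a contig and strand. The metaprofile maps each side of each junction to a
common axis in transcript orientation — offsets −intron_window…−1 in the
flanking intron, +1…+exon_window into the circularized exon (defaults
250/50; the 1000-nt intronic variant is selectable) — and reports the
mean count per offset. Positions beyond contig ends contribute zero while
the junction still counts, so Σ(position means) × n_junctions equals the
total overlapped signal exactly on integer input. Curve smoothing is
presentation-layer and out of scope.

## Differential-expression preparation

The combined matrix stacks raw gene counts (genes with a total of ≥ 10
reads, configurable) and raw circRNA back-splice counts, with
coordinate-derived circ row ids (`circ|contig:start-end(strand)`) that
cannot collide with gene ids. All rows are exported, so the external
engine's size-factor estimation sees the full library. Eligibility for
testing is the high-confidence rule applied within a single sample group
(e.g. one cell line). The engine's model fitting is out of scope; results
are joined back with a three-state status (significant / not significant
at the FDR threshold, default 0.1 / untested), because "untested" must
never be conflated with "not significant".

## The simulator

The generator emulates junction *evidence*, not reads: chimeric records,
SJ tables, caller-style candidate files and repeat tracks, all derived
from one `random.Random(seed)` stream (integer draws only), so a fixed
configuration is byte-identical across runs and platforms. Defaults
describe the benchmark conditions: 20 genes of 4–8 exons (exons
80–300 nt, introns 500–2000 nt) across contigs of 5 genes each, 30
planted circRNAs at annotated internal exon boundaries, 2–8 distinct
reads per sample across 4 samples in 2 conditions, a 0.2 duplicate rate,
0–20 linear-junction reads per intron, library size 10⁶, and 5 artifacts
per category:

* **long span** — junctions > 100 kb on a dedicated gene-free contig;
* **non-canonical motif** — strand-flipped junctions at genuine exon
  boundaries, whose motif context is deterministically non-canonical
  when read from the wrong strand;
* **multi-gene** — junctions joining internal exon boundaries of two
  adjacent same-strand genes (motifs stay canonical, so only the
  multi-gene rule fires);
* **low support** — a single distinct read plus one coordinate-identical
  duplicate, exercising the dedup-based presence rule.

Each artifact passes every rule earlier in the cascade than its own, so
the per-rule rejection tallies equal the planted counts exactly. Planted
inverted repeats (50 nt, A-padded so the recovered alignment is exactly
the planted copy) and Alu-like repeat annotations decorate the flanking
introns of the first few circRNAs.

Because evidence is planted at exact coordinates with known counts, the
truth table's expected post-filter fate is deterministic, and the master
end-to-end test asserts that prediction equals the pipeline's decision
for every entry. What passing does **not** show: robustness to alignment
noise (soft-clips, small coordinate jitter between callers), mappability
artifacts, expression realism, or sequencing-error effects — the
simulator starts downstream of alignment by design, and near-duplicate
junctions are only reported, not resolved.

## Problem sizes and numerical notes

The benchmark runs (20 genes / 50 planted junctions / 4 samples) complete
in about a second; the counting-oracle comparison uses 10⁴ records ×
10² junctions; metric identities are checked on 10⁴ random pairs at
1e−9 absolute tolerance; TPM column sums at 1e−6 relative tolerance.
Catalog TSVs serialize floats with `repr` so round-trips are exact.
Ties in parental-transcript choice and canonical output order
(contig, start, end, strand) are deterministic everywhere.
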