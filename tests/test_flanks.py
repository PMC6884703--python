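"""Flanking-sequence analyses: repeat-pair orientation, inverted
complementarity via local alignment, crosslink merging, metaprofiles."""

from __future__ import annotations

import random

import pytest

from circkit.core import (
    BackspliceJunction,
    CrosslinkSite,
    GenomeSequence,
    RepeatFeature,
    Strand,
    reverse_complement,
)
from circkit.flanks import (
    inverted_complementarity,
    merge_crosslink_sites,
    repeat_pair_orientation,
    signal_metaprofile,
)


def J(start, end, strand=Strand.PLUS, contig="chr1"):
    return BackspliceJunction(contig, start, end, strand)


def alu(start, end, strand):
    return RepeatFeature("chr1", start, end, strand, "AluY", "SINE/Alu")


class TestRepeatPairOrientation:
    def test_opposite_strands_are_inverted(self):
        result = repeat_pair_orientation(
            J(10_000, 20_000),
            [alu(9_600, 9_900, Strand.PLUS), alu(20_100, 20_400, Strand.MINUS)],
        )
        assert result.orientation == "inverted"

    def test_same_strand_pair(self):
        result = repeat_pair_orientation(
            J(10_000, 20_000),
            [alu(9_600, 9_900, Strand.PLUS), alu(20_100, 20_400, Strand.PLUS)],
        )
        assert result.orientation == "same"

    def test_empty_downstream_window_is_none(self):
        result = repeat_pair_orientation(J(10_000, 20_000), [alu(9_600, 9_900, Strand.PLUS)])
        assert result.orientation == "none"
        assert result.upstream_has_repeat and not result.downstream_has_repeat

    def test_mixed_pairs_inverted_dominates(self):
        result = repeat_pair_orientation(
            J(10_000, 20_000),
            [
                alu(9_600, 9_900, Strand.PLUS),
                alu(20_100, 20_200, Strand.PLUS),
                alu(20_250, 20_400, Strand.MINUS),
            ],
        )
        assert result.orientation == "inverted"

    def test_non_family_repeats_ignored(self):
        line = RepeatFeature("chr1", 9_600, 9_900, Strand.PLUS, "L1MC", "LINE/L1")
        result = repeat_pair_orientation(J(10_000, 20_000), [line, alu(20_100, 20_400, Strand.MINUS)])
        assert result.orientation == "none"

    def test_window_outside_500_nt_not_counted(self):
        result = repeat_pair_orientation(
            J(10_000, 20_000),
            [alu(9_000, 9_400, Strand.PLUS), alu(20_600, 20_900, Strand.MINUS)],
        )
        assert result.orientation == "none"


def _genome_with_planted_repeat(seed: int, repeat_len: int):
    """15 kb genome; junction (5000, 9000); repeat planted 100 nt outside
    each boundary, downstream copy reverse-complemented."""
    rng = random.Random(seed)
    seq = list("".join(rng.choice("ACGT") for _ in range(15_000)))
    repeat = "".join(rng.choice("ACGT") for _ in range(repeat_len))
    # pad with A on both sides of both copies: A pairs with T after
    # reverse complementation, so the local alignment cannot extend past
    # the planted repeat by chance
    padded_up = "AAAA" + repeat + "AAAA"
    padded_down = "AAAA" + reverse_complement(repeat) + "AAAA"
    up_start = 5000 - 100 - len(padded_up)
    seq[up_start : up_start + len(padded_up)] = padded_up
    seq[9100 : 9100 + len(padded_down)] = padded_down
    return GenomeSequence({"chr1": "".join(seq)}), J(5000, 9000)


class TestInvertedComplementarity:
    def test_planted_fifty_nt_repeat_is_flagged(self):
        genome, junction = _genome_with_planted_repeat(101, 50)
        result = inverted_complementarity(junction, genome)
        assert result.length >= 50
        assert result.percent_identity == 100.0
        assert result.complementary

    def test_thirty_nine_nt_repeat_is_below_length_threshold(self):
        genome, junction = _genome_with_planted_repeat(103, 39)
        result = inverted_complementarity(junction, genome)
        assert not result.complementary

    def test_random_windows_not_complementary(self):
        rng = random.Random(107)
        seq = "".join(rng.choice("ACGT") for _ in range(15_000))
        genome = GenomeSequence({"chr1": seq})
        result = inverted_complementarity(J(5000, 9000), genome)
        assert not result.complementary

    def test_truncated_window_below_ten_nt_is_undefined(self):
        genome = GenomeSequence({"chr1": "ACGT" * 300})
        assert inverted_complementarity(J(5, 600, contig="chr1"), genome) is None

    def test_score_symmetric_under_window_swap(self):
        # swapping the windows with mutual reverse complementation leaves
        # the optimal local alignment score unchanged
        genome, junction = _genome_with_planted_repeat(109, 45)
        upstream = genome.fetch("chr1", junction.start - 500, junction.start)
        downstream = genome.fetch("chr1", junction.end, junction.end + 500)
        swapped = GenomeSequence(
            {
                "chr1": genome.fetch("chr1", 0, junction.start)
                .replace(upstream, reverse_complement(downstream))
                + genome.fetch("chr1", junction.start, junction.end)
                + reverse_complement(upstream)
                + genome.fetch("chr1", junction.end + 500, 15_000)
            }
        )
        original = inverted_complementarity(junction, genome)
        mirrored = inverted_complementarity(junction, swapped)
        assert mirrored.score == original.score


def site(pos, strand=Strand.PLUS, count=1, contig="chr1"):
    return CrosslinkSite(contig, pos, strand, count)


class TestCrosslinkMerging:
    def test_distance_seven_merges(self):
        clusters = merge_crosslink_sites([site(10), site(17)])
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (10, 17)

    def test_distance_nine_stays_separate(self):
        assert len(merge_crosslink_sites([site(10), site(19)])) == 2

    def test_distance_eight_boundary_merges(self):
        assert len(merge_crosslink_sites([site(10), site(18)])) == 1

    def test_chain_merges_transitively(self):
        clusters = merge_crosslink_sites([site(10), site(17), site(24)])
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end, clusters[0].n_sites) == (10, 24, 3)

    def test_strands_do_not_merge(self):
        clusters = merge_crosslink_sites([site(10), site(12, strand=Strand.MINUS)])
        assert len(clusters) == 2

    def test_order_independent_and_merge_is_fixpoint(self):
        rng = random.Random(11)
        sites = [site(rng.randrange(0, 500)) for _ in range(100)]
        a = merge_crosslink_sites(sites)
        rng.shuffle(sites)
        assert merge_crosslink_sites(sites) == a
        # fixpoint: consecutive clusters are separated by more than the
        # merge gap, so no further merging is possible
        for prev, nxt in zip(a, a[1:]):
            assert nxt.start - prev.end > 8
        assert sum(c.n_sites for c in a) == len(sites)


class TestMetaprofile:
    def test_single_site_five_nt_into_upstream_intron(self):
        junction = J(5000, 9000)
        profile = signal_metaprofile([junction], [site(4995)], 250, 50)
        expect = {off: 0.0 for off in profile.offsets}
        expect[-5] = 1.0
        assert dict(zip(profile.offsets, profile.acceptor)) == expect
        assert all(v == 0.0 for v in profile.donor)

    def test_mean_across_junctions_at_shared_offset(self):
        junctions = [J(5000, 9000), J(20_000, 24_000)]
        sites = [site(4995), site(19_995)]
        profile = signal_metaprofile(junctions, sites, 250, 50)
        assert dict(zip(profile.offsets, profile.acceptor))[-5] == 1.0

    def test_translation_equivariance(self):
        junction = J(5000, 9000)
        base = signal_metaprofile([junction], [site(4990)], 250, 50)
        shifted = signal_metaprofile([J(5003, 9003)], [site(4993)], 250, 50)
        assert shifted.acceptor == base.acceptor

    def test_minus_strand_orientation(self):
        # on the minus strand the acceptor's upstream intron is genomically
        # right of the junction end
        junction = J(5000, 9000, strand=Strand.MINUS)
        profile = signal_metaprofile([junction], [site(9004, strand=Strand.MINUS)], 250, 50)
        assert dict(zip(profile.offsets, profile.acceptor))[-5] == 1.0

    def test_conservation_identity_exact_on_integers(self):
        rng = random.Random(13)
        junctions = [J(5000 + 10_000 * i, 9000 + 10_000 * i) for i in range(5)]
        sites = []
        for _ in range(200):
            pos = rng.randrange(0, 60_000)
            sites.append(site(pos, count=rng.randrange(1, 5)))
        intron_w, exon_w = 250, 50
        profile = signal_metaprofile(junctions, sites, intron_w, exon_w)
        # total overlapped signal counted with multiplicity per junction side
        signal = {}
        for s in sites:
            signal[s.position] = signal.get(s.position, 0) + s.count
        total = 0
        for j in junctions:
            for pos in range(j.start - intron_w, j.start + exon_w):
                total += signal.get(pos, 0)  # acceptor axis
            for pos in range(j.end - exon_w, j.end + intron_w):
                total += signal.get(pos, 0)  # donor axis
        assert profile.total_signal() == pytest.approx(total)

    def test_empty_junction_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            signal_metaprofile([], [site(1)], 250, 50)
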