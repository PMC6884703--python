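"""Recounting and abundance metrics: duplicate flagging, the brute-force
counting oracle, metric formulas and their algebraic consistency."""

from __future__ import annotations

import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.core import (
    BackspliceJunction,
    CircRecord,
    LinearJunctionRecord,
    SampleLibrary,
    Strand,
)
from circkit.detect import junction_from_record
from circkit.quantify import (
    clr,
    clr_shift,
    count_backsplice,
    flag_duplicates,
    host_tpm,
    linear_support,
    percent_circularized,
    rpm,
)
from tests.conftest import make_model
from tests.test_detect import make_record


class TestDuplicateFlagging:
    def test_shared_segment_coordinates_flagged(self):
        a = make_record(2000, 999, seg1=(100, "35M"), seg2=(50, "35M"), read_id="a")
        b = make_record(2000, 999, seg1=(100, "35M"), seg2=(50, "35M"), read_id="b")
        c = make_record(2000, 999, seg1=(101, "35M"), seg2=(50, "35M"), read_id="c")
        flagged, n_all, n_distinct = flag_duplicates([a, b, c])
        assert (n_all, n_distinct) == (3, 2)
        assert [dup for _, dup in flagged] == [False, True, False]

    def test_key_is_positional_not_sequence(self):
        # same read id at different positions: both distinct
        a = make_record(2000, 999, seg1=(100, "35M"), read_id="same")
        b = make_record(2000, 999, seg1=(200, "35M"), read_id="same")
        _, n_all, n_distinct = flag_duplicates([a, b])
        assert (n_all, n_distinct) == (2, 2)

    def test_single_record(self):
        _, n_all, n_distinct = flag_duplicates([make_record(2000, 999)])
        assert (n_all, n_distinct) == (1, 1)

    def test_idempotent(self):
        records = [make_record(2000, 999, seg1=(100, "35M"))] * 3
        flagged, _, _ = flag_duplicates(records)
        again, n_all, n_distinct = flag_duplicates([r for r, _ in flagged])
        assert [d for _, d in again] == [d for _, d in flagged]
        assert (n_all, n_distinct) == (3, 1)


class TestCountBacksplice:
    LIBS = [SampleLibrary("S1", "normoxia", 10_000_000), SampleLibrary("S2", "hypoxia", 10_000_000)]

    def test_duplicates_split_all_vs_distinct(self):
        j = BackspliceJunction("chrT", 1000, 2000, Strand.PLUS)
        recs = [
            make_record(2000, 999, seg1=(100, "35M"), seg2=(50, "35M")),
            make_record(2000, 999, seg1=(100, "35M"), seg2=(50, "35M")),  # duplicate
            make_record(2000, 999, seg1=(200, "35M"), seg2=(50, "35M")),
            make_record(2000, 999, seg1=(300, "35M"), seg2=(50, "35M")),
        ]
        counted = count_backsplice([j], recs, self.LIBS)
        assert counted[j.key].all_reads == {"S1": 4, "S2": 0}
        assert counted[j.key].distinct_reads == {"S1": 3, "S2": 0}

    def test_zero_support_junction_retained(self):
        j = BackspliceJunction("chrT", 9000, 9500, Strand.PLUS)
        counted = count_backsplice([j], [], self.LIBS)
        assert counted[j.key].all_reads == {"S1": 0, "S2": 0}

    def test_unknown_sample_is_error(self):
        j = BackspliceJunction("chrT", 1000, 2000, Strand.PLUS)
        with pytest.raises(KeyError, match="S9"):
            count_backsplice([j], [make_record(2000, 999, sample="S9")], self.LIBS)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(41)
        spans = [(1000 * i, 1000 * i + rng.randrange(100, 900)) for i in range(1, 101)]
        junctions = [BackspliceJunction("chrT", s, e, Strand.PLUS) for s, e in spans]
        records = []
        for _ in range(1000):
            s, e = rng.choice(spans + [(57, 400)])  # includes an uncataloged span
            records.append(
                make_record(
                    e, s - 1,
                    sample=rng.choice(["S1", "S2"]),
                    seg1=(rng.randrange(50), "35M"),
                    seg2=(rng.randrange(50), "35M"),
                )
            )
        counted = count_backsplice(junctions, records, self.LIBS)
        for j in junctions:
            for sample in ("S1", "S2"):
                matching = [
                    r for r in records
                    if r.sample_id == sample and junction_from_record(r) == BackspliceJunction(
                        j.contig, j.start, j.end, j.strand)
                ]
                keys = {(r.seg1_pos, r.seg1_cigar, r.seg2_pos, r.seg2_cigar) for r in matching}
                assert counted[j.key].all_reads[sample] == len(matching)
                assert counted[j.key].distinct_reads[sample] == len(keys)


class TestMetricFormulas:
    def test_rpm_formula(self):
        assert rpm(50, 10_000_000) == 5.0
        assert rpm(0, 10_000_000) == 0.0

    def test_rpm_scale_invariance(self):
        assert rpm(2 * 17, 2 * 3_000_000) == rpm(17, 3_000_000)

    def test_rpm_requires_positive_library(self):
        with pytest.raises(ValueError):
            rpm(10, 0)

    @pytest.mark.parametrize(
        "back,linear,expected", [(10, 4, 2.0), (0, 7, 0.0), (7, 0, 7.0)]
    )
    def test_clr_pseudocount_on_denominator(self, back, linear, expected):
        assert clr(back, linear) == expected

    @pytest.mark.parametrize(
        "back,linear,expected", [(5, 5, 50.0), (9, 1, 90.0), (0, 12, 0.0)]
    )
    def test_percent_circularized(self, back, linear, expected):
        assert percent_circularized(back, linear) == expected

    def test_percent_circularized_undefined_when_both_zero(self):
        assert percent_circularized(0, 0) is None

    @settings(max_examples=200, deadline=None)
    @given(back=st.integers(0, 10_000), linear=st.integers(0, 10_000))
    def test_algebraic_consistency_of_clr_and_percent(self, back, linear):
        pct = percent_circularized(back, linear)
        if back + linear == 0:
            assert pct is None
            return
        assert 0.0 <= pct <= 100.0
        if linear > 0:
            raw_ratio = back / linear
            assert abs(pct - 100.0 * raw_ratio / (1.0 + raw_ratio)) < 1e-9


class TestLinearSupport:
    def junction(self):
        return BackspliceJunction("chr1", 1000, 2000, Strand.PLUS)

    def linrec(self, intron_start, intron_end, reads, strand=Strand.PLUS):
        return LinearJunctionRecord(
            contig="chr1", intron_start=intron_start, intron_end=intron_end,
            strand=strand, unique_reads=reads, multi_reads=0,
            annotated_flag=True, sample_id="S1",
        )

    def test_mean_of_both_sides(self):
        # acceptor side: intron ending at start (8 reads); donor side:
        # intron starting at end (4 reads)
        records = [self.linrec(500, 1000, 8), self.linrec(2000, 2500, 4)]
        assert linear_support(self.junction(), records) == 6.0

    def test_no_linear_junctions_gives_zero(self):
        assert linear_support(self.junction(), []) == 0.0

    def test_alternative_partners_sum_per_side(self):
        # two distinct introns share the donor site (3+2), acceptor has 5:
        # mean(5, 5) = 5.0 -- enumerated by hand on this fixture
        records = [
            self.linrec(500, 1000, 5),
            self.linrec(2000, 2500, 3),
            self.linrec(2000, 3000, 2),
        ]
        assert linear_support(self.junction(), records) == 5.0

    def test_other_strand_not_counted(self):
        records = [self.linrec(500, 1000, 8, strand=Strand.MINUS)]
        assert linear_support(self.junction(), records) == 0.0


class TestClrShift:
    LIBS = [
        SampleLibrary("S1", "normoxia", 10**6),
        SampleLibrary("S2", "normoxia", 10**6),
        SampleLibrary("S3", "hypoxia", 10**6),
        SampleLibrary("S4", "hypoxia", 10**6),
    ]

    def record(self, clrs):
        return CircRecord(
            junction=BackspliceJunction("chr1", 1000, 2000, Strand.PLUS),
            clr=clrs,
        )

    def test_twofold_shift(self):
        r = self.record({"S1": 1.0, "S2": 1.0, "S3": 2.0, "S4": 2.0})
        assert clr_shift(r, self.LIBS, "normoxia", "hypoxia") == 2.0

    def test_identical_conditions_give_unity(self):
        r = self.record({"S1": 1.5, "S2": 1.5, "S3": 1.5, "S4": 1.5})
        assert clr_shift(r, self.LIBS, "normoxia", "hypoxia") == 1.0

    def test_zero_baseline_is_infinite(self):
        r = self.record({"S1": 0.0, "S2": 0.0, "S3": 0.5, "S4": 0.5})
        assert math.isinf(clr_shift(r, self.LIBS, "normoxia", "hypoxia"))

    def test_unknown_condition_is_error(self):
        r = self.record({"S1": 1.0, "S2": 1.0, "S3": 1.0, "S4": 1.0})
        with pytest.raises(KeyError):
            clr_shift(r, self.LIBS, "normoxia", "anoxia")


def exon_count_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "S1", "S2"])


class TestHostTpm:
    def models(self):
        return [
            make_model("T1", "G1", "chr1", Strand.PLUS, [(0, 1000), (2000, 3000)]),
            make_model("T2", "G2", "chr1", Strand.PLUS, [(10_000, 11_000), (12_000, 13_000)]),
            make_model("T3", "G3", "chr1", Strand.PLUS, [(20_000, 20_500), (21_000, 21_500)]),
        ]

    def test_single_gene_normalizes_to_million(self):
        counts = exon_count_frame([("G1", "chr1", 0, 1000, 37, 11),
                                   ("G1", "chr1", 2000, 3000, 5, 2)])
        result = host_tpm(counts, self.models()[:1], set())
        assert result["G1"].tpm["S1"] == pytest.approx(1e6)
        assert result["G1"].tpm["S2"] == pytest.approx(1e6)

    def test_symmetric_genes_split_evenly(self):
        counts = exon_count_frame([
            ("G1", "chr1", 0, 1000, 10, 10), ("G1", "chr1", 2000, 3000, 10, 10),
            ("G2", "chr1", 10_000, 11_000, 10, 10), ("G2", "chr1", 12_000, 13_000, 10, 10),
        ])
        result = host_tpm(counts, self.models(), set())
        assert result["G1"].tpm["S1"] == pytest.approx(5e5)
        assert result["G2"].tpm["S1"] == pytest.approx(5e5)

    def test_three_gene_fixture_matches_hand_computation(self):
        # internal exon (G1 exon 2) removed from counts AND length:
        # rates S1: G1 = 40/1.0, G2 = 30/2.0, G3 = 10/1.0 -> total 65
        counts = exon_count_frame([
            ("G1", "chr1", 0, 1000, 40, 0), ("G1", "chr1", 2000, 3000, 99, 99),
            ("G2", "chr1", 10_000, 11_000, 12, 0), ("G2", "chr1", 12_000, 13_000, 18, 0),
            ("G3", "chr1", 20_000, 20_500, 4, 0), ("G3", "chr1", 21_000, 21_500, 6, 0),
        ])
        internal = {("chr1", 2000, 3000)}
        result = host_tpm(counts, self.models(), internal)
        total = 40 / 1.0 + 30 / 2.0 + 10 / 1.0
        assert result["G1"].tpm["S1"] == pytest.approx(40 / 1.0 / total * 1e6)
        assert result["G2"].tpm["S1"] == pytest.approx(30 / 2.0 / total * 1e6)
        assert result["G3"].tpm["S1"] == pytest.approx(10 / 1.0 / total * 1e6)

    def test_fully_internal_gene_warns_and_gets_zero(self):
        counts = exon_count_frame([
            ("G1", "chr1", 0, 1000, 40, 1), ("G1", "chr1", 2000, 3000, 10, 1),
            ("G3", "chr1", 20_000, 20_500, 5, 1), ("G3", "chr1", 21_000, 21_500, 5, 1),
        ])
        internal = {("chr1", 20_000, 20_500), ("chr1", 21_000, 21_500)}
        with pytest.warns(UserWarning, match="circle-internal"):
            result = host_tpm(counts, self.models(), internal)
        assert result["G3"].tpm["S1"] == 0.0
        assert result["G1"].tpm["S1"] == pytest.approx(1e6)

    def test_unannotated_exon_is_error(self):
        counts = exon_count_frame([("G1", "chr1", 123, 456, 1, 1)])
        with pytest.raises(KeyError):
            host_tpm(counts, self.models(), set())

    def test_column_sums_are_one_million(self):
        rng = random.Random(47)
        rows = []
        for gene, spans in (("G1", [(0, 1000), (2000, 3000)]),
                            ("G2", [(10_000, 11_000), (12_000, 13_000)]),
                            ("G3", [(20_000, 20_500), (21_000, 21_500)])):
            for s, e in spans:
                rows.append((gene, "chr1", s, e, rng.randrange(1, 100), rng.randrange(1, 100)))
        result = host_tpm(exon_count_frame(rows), self.models(), {("chr1", 2000, 3000)})
        for sample in ("S1", "S2"):
            total = sum(g.tpm[sample] for g in result.values())
            assert total == pytest.approx(1e6, rel=1e-6)
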