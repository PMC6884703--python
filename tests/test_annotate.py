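"""Annotation against the hand-built multi-gene fixture: parental
transcript choice, internal structure, origin classes, rank spectra,
alternative back-splicing and length features."""

from __future__ import annotations

import random

import pytest

from circkit.core import (
    BackspliceJunction,
    CircAnnotation,
    CircRecord,
    Strand,
)
from circkit.annotate import (
    alt_backsplice_summary,
    assign_parental_transcript,
    exon_rank_spectrum,
    length_features,
)
from tests.conftest import make_model


def J(start, end, strand=Strand.PLUS, contig="chr1"):
    return BackspliceJunction(contig, start, end, strand)


class TestParentalAssignment:
    def test_canonical_both_sides_match(self, toy_models):
        # junction at exon 2 start / exon 4 end of the canonical TA1
        annotation = assign_parental_transcript(J(2200, 4800), toy_models)
        assert annotation.parental_transcript_id == "TA1"
        assert (annotation.acceptor_exon_rank, annotation.donor_exon_rank) == (2, 4)
        assert [(e.start, e.end) for e in annotation.internal_exons] == [
            (2200, 2400), (3400, 3600), (4600, 4800)
        ]
        assert annotation.spliced_length == 200 + 200 + 200

    def test_both_sides_match_beats_canonical_one_side(self, toy_models):
        # 3650 is a TA2-only boundary; TA1 (canonical) matches only the
        # acceptor side, so the non-canonical both-sides match wins.
        annotation = assign_parental_transcript(J(2200, 3650), toy_models)
        assert annotation.parental_transcript_id == "TA2"

    def test_intronic_junction(self, toy_models):
        annotation = assign_parental_transcript(J(1300, 2100), toy_models)
        assert annotation.origin_class == "intronic"
        assert annotation.parental_transcript_id is None

    def test_intergenic_junction(self, toy_models):
        annotation = assign_parental_transcript(J(7000, 8000), toy_models)
        assert annotation.origin_class == "intergenic"

    def test_overlapping_genes_are_ambiguous(self, toy_models):
        # GB (+) and GC (-) overlap; a span across both is ambiguous
        annotation = assign_parental_transcript(J(11200, 12600), toy_models)
        assert annotation.origin_class == "ambiguous"

    def test_disjoint_genes_are_multi_gene(self, toy_models):
        annotation = assign_parental_transcript(J(2200, 12600), toy_models)
        assert annotation.origin_class == "multi_gene"

    def test_transcript_input_order_does_not_matter(self, toy_models):
        rng = random.Random(3)
        junctions = [J(2200, 4800), J(2200, 3650), J(1000, 2400), J(1300, 2100)]
        baseline = [assign_parental_transcript(j, toy_models) for j in junctions]
        for _ in range(5):
            shuffled = list(toy_models)
            rng.shuffle(shuffled)
            assert [assign_parental_transcript(j, shuffled) for j in junctions] == baseline


class TestOriginClasses:
    def test_both_boundaries_in_cds(self, toy_models):
        annotation = assign_parental_transcript(J(2200, 4800), toy_models)
        assert (annotation.acceptor_region, annotation.donor_region) == ("CDS", "CDS")
        assert annotation.origin_class == "CDS"

    def test_acceptor_in_utr5(self, toy_models):
        # exon 1 starts at 1000 but CDS starts at 1100
        annotation = assign_parental_transcript(J(1000, 2400), toy_models)
        assert annotation.acceptor_region == "UTR5"
        assert annotation.donor_region == "CDS"
        assert annotation.origin_class == "UTR5"

    def test_noncoding_transcript_boundaries(self, toy_models):
        # single-exon circle in GB's first exon; GB has no CDS annotated
        annotation = assign_parental_transcript(J(10000, 10200), toy_models)
        assert annotation.origin_class == "exonic_noncoding"
        assert annotation.parental_transcript_id == "TB1"


class TestExonRankSpectrum:
    def rank_models(self):
        def exons(n, origin):
            return [(origin + 1000 * i, origin + 1000 * i + 200) for i in range(n)]

        return [
            make_model("R1", "GR1", "chr8", Strand.PLUS, exons(3, 0)),
            make_model("R2", "GR2", "chr8", Strand.PLUS, exons(4, 50_000)),
            make_model("R3", "GR3", "chr8", Strand.PLUS, exons(6, 100_000)),
        ]

    def annotation(self, acceptor, donor):
        return CircAnnotation(
            origin_class="CDS", parental_transcript_id="R3", gene_id="GR3",
            acceptor_exon_rank=acceptor, donor_exon_rank=donor,
        )

    def test_documented_fixture_two_thirds(self):
        # genes with 3/4/6 exons; two circRNAs with acceptor rank 2:
        # denominator = genes with >= 3 exons = 3 -> 2/3
        spectrum = exon_rank_spectrum(
            [self.annotation(2, 2), self.annotation(2, 3)], self.rank_models()
        )
        assert spectrum["acceptor"][2] == pytest.approx(2 / 3)
        # donor rank 2 -> 1/3; donor rank 3 -> genes with >= 4 exons = 2 -> 1/2
        assert spectrum["donor"][2] == pytest.approx(1 / 3)
        assert spectrum["donor"][3] == pytest.approx(1 / 2)

    def test_rank_without_eligible_genes_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="omitted"):
            spectrum = exon_rank_spectrum([self.annotation(6, 6)], self.rank_models())
        assert 6 not in spectrum["acceptor"]

    def test_empty_input_gives_empty_spectrum(self):
        spectrum = exon_rank_spectrum([], self.rank_models())
        assert spectrum == {"acceptor": {}, "donor": {}}

    def test_denominator_monotone_in_rank(self, sim_dataset, sim_pipeline):
        from circkit.annotate import annotate_catalog

        catalog = annotate_catalog(list(sim_pipeline.catalog), sim_dataset.transcripts)
        spectrum = exon_rank_spectrum(
            [r.annotation for r in catalog], sim_dataset.transcripts
        )
        # reconstruct denominators: frequency/normalized must be driven by
        # a non-increasing gene count in r
        gene_counts = {}
        for m in sim_dataset.transcripts:
            gene_counts[m.gene_id] = max(gene_counts.get(m.gene_id, 0), m.n_exons)
        denominators = [
            sum(1 for n in gene_counts.values() if n >= r + 1)
            for r in sorted(spectrum["acceptor"])
        ]
        assert denominators == sorted(denominators, reverse=True)


class TestAltBacksplicing:
    def record(self, start, end, gene="GA"):
        rec = CircRecord(junction=J(start, end))
        rec.annotation = CircAnnotation(origin_class="CDS", gene_id=gene,
                                        parental_transcript_id="T")
        return rec

    def test_shared_acceptor_flags_site_alternative(self):
        # junctions (a,b) and (a,c): 2 isoforms; site a alternative
        catalog = [self.record(2200, 4800), self.record(2200, 3600)]
        summary = alt_backsplice_summary(catalog)
        assert summary.isoforms_per_gene == {"GA": 2}
        acceptor = ("chr1", "+", 2200, "acceptor")
        assert summary.alternative_sites[acceptor]
        donors = [s for s in summary.alternative_sites if s[3] == "donor"]
        assert all(not summary.alternative_sites[s] for s in donors)

    def test_single_junction_gene_has_no_alternatives(self):
        summary = alt_backsplice_summary([self.record(2200, 4800)])
        assert summary.isoforms_per_gene == {"GA": 1}
        assert not any(summary.alternative_sites.values())

    def test_many_isoform_fixture_matches_hand_enumeration(self):
        # one gene, acceptors {a1, a2}, donors {d1..d4}; junctions pair
        # a1 with all four donors and a2 with d1 only
        a1, a2 = 1000, 1400
        donors = [3000, 3400, 3800, 4200]
        catalog = [self.record(a1, d) for d in donors] + [self.record(a2, donors[0])]
        summary = alt_backsplice_summary(catalog)
        assert summary.isoforms_per_gene == {"GA": 5}
        assert summary.site_partner_counts[("chr1", "+", a1, "acceptor")] == 4
        assert summary.site_partner_counts[("chr1", "+", a2, "acceptor")] == 1
        assert summary.site_partner_counts[("chr1", "+", donors[0], "donor")] == 2
        # 1 of 2 acceptor sites alternative; 1 of 4 donor sites alternative
        assert summary.fraction_alternative_acceptor == pytest.approx(1 / 2)
        assert summary.fraction_alternative_donor == pytest.approx(1 / 4)


class TestLengthFeatures:
    def test_kilobase_flanking_introns(self, toy_models):
        annotation = assign_parental_transcript(J(2200, 4800), toy_models)
        annotation = length_features(annotation, J(2200, 4800), toy_models)
        assert annotation.upstream_intron_length == 1000
        assert annotation.downstream_intron_length == 1000
        assert annotation.genomic_span == 2600
        assert annotation.spliced_length == 600

    def test_single_exon_circle(self, toy_models):
        annotation = assign_parental_transcript(J(2200, 2400), toy_models)
        annotation = length_features(annotation, J(2200, 2400), toy_models)
        assert annotation.spliced_length == 200  # == exon length

    def test_first_exon_has_no_upstream_intron(self, toy_models):
        annotation = assign_parental_transcript(J(1000, 2400), toy_models)
        annotation = length_features(annotation, J(1000, 2400), toy_models)
        assert annotation.upstream_intron_length is None
        assert annotation.downstream_intron_length == 1000

    def test_internal_exons_form_contiguous_rank_block(self, sim_dataset, sim_pipeline):
        from circkit.annotate import annotate_catalog

        catalog = annotate_catalog(list(sim_pipeline.catalog), sim_dataset.transcripts)
        for rec in catalog:
            a = rec.annotation
            ranks = [e.rank for e in a.internal_exons]
            assert ranks == list(range(a.acceptor_exon_rank, a.donor_exon_rank + 1))
            assert a.spliced_length <= a.genomic_span
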