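"""Shared fixtures: a seeded simulated dataset, its pipeline run, and a
hand-built multi-gene annotation used by the annotation tests."""

from __future__ import annotations

import pytest

from circkit.core import ExonInterval, GenomeSequence, Strand, TranscriptModel
from circkit.pipeline import run_pipeline
from circkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset():
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_pipeline(sim_dataset):
    ds = sim_dataset
    return run_pipeline(
        ds.all_chimeric(),
        ds.all_linear(),
        ds.genome,
        ds.transcripts,
        ds.libraries,
        [ds.findcirc_candidates, ds.circexplorer_candidates],
        min_overhang=15,
        filter_config=ds.config.filter_config,
    )


def make_model(
    transcript_id: str,
    gene_id: str,
    contig: str,
    strand: Strand,
    exon_coords: list[tuple[int, int]],
    canonical: bool = True,
    cds: list[tuple[int, int]] | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_name=gene_id,
        contig=contig,
        strand=strand,
        exons=[ExonInterval(contig, s, e, rank=1) for s, e in exon_coords],
        canonical_flag=canonical,
        cds_intervals=sorted(cds) if cds else [],
    )


@pytest.fixture(scope="session")
def toy_models():
    """Hand-built annotation on one contig.

    * GA (+, canonical TA1 with 5 exons and 1 kb introns, CDS mid-e1 to
      mid-e5; non-canonical TA2 sharing most boundaries but ending exon 3
      at 3650).
    * GB (+, 3 exons) disjoint from GA.
    * GC (-, 3 exons) overlapping GB.
    """
    ta1 = make_model(
        "TA1", "GA", "chr1", Strand.PLUS,
        [(1000, 1200), (2200, 2400), (3400, 3600), (4600, 4800), (5800, 6000)],
        canonical=True,
        cds=[(1100, 1200), (2200, 2400), (3400, 3600), (4600, 4800), (5800, 5900)],
    )
    ta2 = make_model(
        "TA2", "GA", "chr1", Strand.PLUS,
        [(1000, 1200), (2200, 2400), (3400, 3650), (4600, 4800)],
        canonical=False,
        cds=[(1100, 1200), (2200, 2400), (3400, 3650), (4600, 4700)],
    )
    tb1 = make_model(
        "TB1", "GB", "chr1", Strand.PLUS,
        [(10000, 10200), (11200, 11400), (12400, 12600)],
        canonical=True,
    )
    tc1 = make_model(
        "TC1", "GC", "chr1", Strand.MINUS,
        [(11000, 11100), (12000, 12100), (13000, 13100)],
        canonical=True,
    )
    return [ta1, ta2, tb1, tc1]


@pytest.fixture()
def toy_genome():
    """60-nt contig with a planted AG..GT back-splice context on +.

    Layout: positions 0-19 filler, acceptor context AG at [18,20) so a
    junction start at 20 reads AG; donor GT at [40,42) so a junction end
    at 40 reads GT.
    """
    seq = "A" * 18 + "AG" + "C" * 20 + "GT" + "A" * 20
    return GenomeSequence({"chrT": seq})
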