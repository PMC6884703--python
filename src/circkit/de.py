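"""Combined circRNA + gene count matrix for an external differential-
expression engine.

Raw back-splice read counts are appended to the per-gene read counts so
the engine estimates size factors and dispersions from the full library
rather than from the sparse circRNA rows alone. The negative-binomial
model fitting itself is delegated to the established engine (DESeq2-style
workflow); this module owns matrix construction, testing eligibility,
export/import and the significance join.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import CircRecord

__all__ = [
    "CountMatrix",
    "build_combined_matrix",
    "de_candidate_table",
    "export_de_inputs",
    "import_de_results",
    "circ_row_id",
]


def circ_row_id(record: CircRecord) -> str:
    """Coordinate-derived row id, collision-free with gene ids."""
    return "circ|" + record.junction.name


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # rows: gene + circ ids; columns: samples; int counts
    row_type: pd.Series  # "gene" | "circ" per row

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids: {dupes}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


def build_combined_matrix(
    gene_counts: pd.DataFrame,
    catalog: list[CircRecord],
    min_gene_total: int = 10,
) -> CountMatrix:
    """Stack gene counts and raw circRNA back-splice counts.

    ``gene_counts`` is genes x samples with raw integer counts; genes
    whose total across samples is below ``min_gene_total`` are dropped.
    The sample sets of the two inputs must agree exactly.
    """
    circ_samples = sorted({s for r in catalog for s in r.all_reads})
    gene_samples = sorted(map(str, gene_counts.columns))
    if catalog and circ_samples != gene_samples:
        diff = set(circ_samples) ^ set(gene_samples)
        raise ValueError(f"sample mismatch between gene counts and catalog: {sorted(diff)}")
    genes = gene_counts.loc[gene_counts.sum(axis=1) >= min_gene_total].astype(int)
    circ_ids = [circ_row_id(r) for r in catalog]
    if len(set(circ_ids)) != len(circ_ids):
        dupes = sorted({c for c in circ_ids if circ_ids.count(c) > 1})
        raise ValueError(f"duplicate circRNA ids in catalog: {dupes}")
    circ_rows = pd.DataFrame(
        [[r.all_reads.get(s, 0) for s in gene_counts.columns] for r in catalog],
        index=circ_ids,
        columns=gene_counts.columns,
        dtype=int,
    )
    counts = pd.concat([genes, circ_rows])
    row_type = pd.Series(
        ["gene"] * len(genes) + ["circ"] * len(circ_rows), index=counts.index
    )
    return CountMatrix(counts=counts, row_type=row_type)


def de_candidate_table(
    catalog: list[CircRecord],
    sample_groups: dict[str, str],
    min_reads: int = 5,
    min_samples: int = 2,
) -> list[CircRecord]:
    """circRNAs eligible for differential testing.

    The high-confidence rule (>= min_reads back-splice reads in >=
    min_samples samples) applied within a single group (cell line /
    dataset): samples from different groups cannot jointly satisfy it.
    """
    for rec in catalog:
        unknown = set(rec.all_reads) - set(sample_groups)
        if unknown:
            raise KeyError(f"samples {sorted(unknown)} missing from sample_groups")
    eligible = []
    groups = sorted(set(sample_groups.values()))
    for rec in catalog:
        for group in groups:
            n_ok = sum(
                1
                for s, n in rec.all_reads.items()
                if sample_groups[s] == group and n >= min_reads
            )
            if n_ok >= min_samples:
                eligible.append(rec)
                break
    return eligible


def export_de_inputs(matrix: CountMatrix, design: dict[str, str], path_prefix) -> tuple[str, str]:
    """Write the count matrix and design table as TSVs for the DE engine.

    ``design`` maps sample id -> condition label. Returns the two paths.
    """
    missing = set(map(str, matrix.counts.columns)) - set(design)
    if missing:
        raise ValueError(f"samples without design entry: {sorted(missing)}")
    counts_path = f"{path_prefix}.counts.tsv"
    design_path = f"{path_prefix}.design.tsv"
    out = matrix.counts.copy()
    out.insert(0, "row_type", matrix.row_type)
    out.to_csv(counts_path, sep="\t", index_label="id")
    pd.DataFrame(
        {"sample": list(matrix.counts.columns),
         "condition": [design[str(s)] for s in matrix.counts.columns]}
    ).to_csv(design_path, sep="\t", index=False)
    return counts_path, design_path


def import_de_results(
    path, catalog: list[CircRecord], fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Join DE-engine results back onto the catalog.

    The results TSV needs columns id, log2FoldChange, padj. Every catalog
    row is preserved: rows without a result are marked "untested" (a
    three-state contract distinct from "not_significant"). Result ids
    absent from the catalog produce a warning list in the "orphans"
    attribute of the returned frame.
    """
    import warnings

    results = pd.read_csv(path, sep="\t")
    results["id"] = results["id"].astype(str)
    results = results.set_index("id")
    rows = []
    catalog_ids = set()
    for rec in catalog:
        cid = circ_row_id(rec)
        catalog_ids.add(cid)
        if cid in results.index:
            lfc = results.at[cid, "log2FoldChange"]
            padj = results.at[cid, "padj"]
            if pd.isna(padj):
                status = "untested"
            else:
                status = "significant" if padj < fdr_threshold else "not_significant"
            rows.append((cid, rec.name, lfc, padj, status))
        else:
            rows.append((cid, rec.name, float("nan"), float("nan"), "untested"))
    joined = pd.DataFrame(
        rows, columns=["id", "junction", "log2FoldChange", "padj", "status"]
    ).set_index("id")
    orphans = sorted(set(results.index) - catalog_ids)
    if orphans:
        warnings.warn(f"result ids absent from catalog: {orphans}", stacklevel=2)
    joined.attrs["orphans"] = orphans
    return joined
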