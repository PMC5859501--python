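#!/usr/bin/env python
"""Enrichment statistics for the differential peak sets.

Fisher exact tests of: proximity of differential peaks to DE genes
(10-kb windows); functional-category composition of genes near
differential vs non-differential peaks (BH-adjusted); and expression
class / temporal cluster membership of DE genes near the overlapping
differential peaks.
"""

from pathlib import Path

import pandas as pd

from peakdiff import io
from peakdiff.annotation import genes_within_window
from peakdiff.enrichment import (
    ExpressionProfile,
    assign_expression_class,
    assign_temporal_cluster,
    category_enrichment,
    class_enrichment,
    enrichment_table,
    proximity_enrichment,
)
from peakdiff.intervals import PeakSet

DATA = Path("results/dataset")
OUT = Path("results")
WINDOW = 10_000


def gene_set_near(peaks, genes):
    out = set()
    for iv in peaks:
        out |= genes_within_window(iv, genes, WINDOW)
    return out


def main() -> None:
    genes = io.read_gff3(DATA / "genes.gff3")
    de_ids = set(pd.read_csv(DATA / "de_genes.tsv", sep="\t")["gene_id"])
    results = []

    diff = {a: io.read_bed(OUT / f"differential_{a}.bed") for a in ("atac", "dnase")}
    rps = {a: io.read_bed(OUT / f"rps_{a}.bed") for a in ("atac", "dnase")}
    for assay in ("atac", "dnase"):
        r = proximity_enrichment(diff[assay], rps[assay], genes, de_ids, WINDOW)
        r.property_name = f"{assay}_diff_within_10kb_of_DE_gene"
        results.append(r)
        t = r.table
        print(
            f"{assay}: {t.a}/{t.a + t.b} differential vs "
            f"{t.c}/{t.c + t.d} non-differential peaks near DE genes "
            f"({r.fold_enrichment:.2f}-fold, p={r.p_value:.3g})"
        )

    cat_df = pd.read_csv(DATA / "categories.tsv", sep="\t")
    cat_map = {}
    for row in cat_df.itertuples():
        cat_map.setdefault(row.gene_id, []).append(row.category)
    near_diff = gene_set_near(diff["atac"], genes) | gene_set_near(
        diff["dnase"], genes
    )
    diff_ids = {iv.id for iv in diff["atac"]}
    nondiff = PeakSet([iv for iv in rps["atac"] if iv.id not in diff_ids])
    near_nondiff = gene_set_near(nondiff, genes) - near_diff
    results.extend(category_enrichment(near_diff, near_nondiff, cat_map))

    expr = pd.read_csv(DATA / "expression.tsv", sep="\t", index_col=0)
    tcols = [c for c in expr.columns if c.startswith("t")]
    profiles = {
        gid: ExpressionProfile(gid, float(row["fpkm_24hpf"]),
                               {float(c[1:]): float(row[c]) for c in tcols})
        for gid, row in expr.iterrows()
    }
    de_class = {g: assign_expression_class(profiles[g].fpkm_24hpf)
                for g in de_ids if g in profiles}
    de_cluster = {g: str(assign_temporal_cluster(profiles[g])) for g in de_ids
                  if g in profiles and assign_temporal_cluster(profiles[g])}
    overlap = io.read_bed(OUT / "overlapping_differential.bed")
    near_overlap = gene_set_near(overlap, genes) & de_ids
    if near_overlap:
        for r in class_enrichment(near_overlap, de_class):
            r.property_name = f"expression_class_{r.property_name}"
            results.append(r)
        for r in class_enrichment(near_overlap, de_cluster):
            r.property_name = f"temporal_cluster_{r.property_name}"
            results.append(r)

    enrichment_table(results).to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'enrichment.tsv'} ({len(results)} tests)")


if __name__ == "__main__":
    main()
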