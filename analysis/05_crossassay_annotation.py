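#!/usr/bin/env python
"""Merge differential peaks supported by both assays and annotate them.

The cross-assay merge (75% non-reciprocal overlap, pooled and
union-merged) yields the high-confidence candidate CRM set.  Each
differential peak is then classified against its closest gene
(Promoter / WithinGeneBody / Upstream / Downstream / Distal) and the
location distribution of the whole RPS is tabulated.
"""

from pathlib import Path

import pandas as pd

from peakdiff import io
from peakdiff.annotation import annotate_peaks, location_distribution
from peakdiff.intervals import OverlapCriterion, cross_assay_merge

DATA = Path("results/dataset")
OUT = Path("results")


def main() -> None:
    diff_atac = io.read_bed(OUT / "differential_atac.bed")
    diff_dnase = io.read_bed(OUT / "differential_dnase.bed")
    overlap = cross_assay_merge(diff_atac, diff_dnase,
                                OverlapCriterion(min_fraction=0.75))
    io.write_bed(overlap, OUT / "overlapping_differential.bed")

    genes = io.read_gff3(DATA / "genes.gff3")
    rows = []
    for assay, peaks in (("atac", diff_atac), ("dnase", diff_dnase)):
        for a in annotate_peaks(peaks, genes):
            rows.append(
                {"assay": assay, "peak_id": a.peak_id, "category": a.category,
                 "subcategory": a.subcategory, "nearest_gene": a.nearest_gene,
                 "distance_bp": a.distance_bp,
                 "genes_within_10kb": ",".join(sorted(a.genes_within_10kb))}
            )
    pd.DataFrame(rows).to_csv(OUT / "annotation.tsv", sep="\t", index=False)

    rps = io.read_bed(OUT / "rps_atac.bed")
    dist = location_distribution(rps, genes)
    dist.to_csv(OUT / "location_distribution_atac_rps.tsv", sep="\t", index=False)

    print(
        f"{len(diff_atac)} ATAC + {len(diff_dnase)} DNase differential peaks "
        f"-> {len(overlap)} overlapping differential peaks (high-confidence set)"
    )
    print(dist.to_string(index=False))


if __name__ == "__main__":
    main()
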