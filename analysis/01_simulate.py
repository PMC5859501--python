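#!/usr/bin/env python
"""Generate the synthetic two-assay accessibility dataset.

Writes the toy genome, gene models, expression table, per-sample peak
calls, count matrices, motif file and the ground-truth manifest under
results/dataset/ — the inputs every later analysis step reads back.
"""

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from peakdiff import io
from peakdiff.motifs import write_meme
from peakdiff.simulate import SimulationConfig, simulate_all

DATA = Path("results/dataset")


def main() -> None:
    cfg = SimulationConfig(seed=1)
    ds = simulate_all(cfg)
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "peaks").mkdir(exist_ok=True)

    io.write_fasta(ds.genome, DATA / "genome.fa")
    io.write_chrom_sizes(ds.sizes, DATA / "genome.sizes")
    io.write_gff3(ds.genes, DATA / "genes.gff3")
    io.write_bed(ds.master_peaks, DATA / "master_peaks.bed")
    for (assay, cond, rep), ps in ds.replicate_peaks.items():
        io.write_bed(ps, DATA / "peaks" / f"{assay}_{cond}_r{rep}.bed")
    for assay in ds.counts:
        io.write_count_matrix(ds.counts[assay], DATA / f"counts_{assay}.tsv")
        pd.DataFrame([asdict(s) for s in ds.samples[assay]]).to_csv(
            DATA / f"samples_{assay}.tsv", sep="\t", index=False
        )
    ds.expression.to_csv(DATA / "expression.tsv", sep="\t")
    with open(DATA / "categories.tsv", "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid, cats in sorted(ds.categories.items()):
            for c in cats:
                fh.write(f"{gid}\t{c}\n")
    pd.DataFrame({"gene_id": sorted(ds.truth.de_gene_ids)}).to_csv(
        DATA / "de_genes.tsv", sep="\t", index=False
    )
    write_meme(ds.pwms, DATA / "motifs.meme")
    io.write_json(ds.manifest(), DATA / "ground_truth.json")

    print(
        f"dataset: {sum(ds.sizes.values()):,} bp genome over "
        f"{len(ds.sizes)} scaffolds; {len(ds.genes)} genes "
        f"({len(ds.truth.de_gene_ids)} DE); {len(ds.master_peaks)} peaks "
        f"({len(ds.truth.differential_peak_ids)} differential, "
        f"{len(ds.truth.motif_planted_peak_ids)} carrying the planted "
        f"{ds.pwms[0].motif_id} site)"
    )
    print(f"wrote {DATA}/")


if __name__ == "__main__":
    main()
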