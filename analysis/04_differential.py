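#!/usr/bin/env python
"""Call differential peaks per assay with the NB Wald test.

Counts are mapped onto the RPS, depth-equalized, normalized with
median-of-ratios size factors, and tested peak by peak; selection uses
the nominal thresholds of the two designs (p < 0.2 for the 2-3
replicate cell-sorted ATAC design, p < 0.1 for the ablation DNase
design), enriched in the target condition.  Recall/precision against
the planted truth are reported.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from peakdiff import io
from peakdiff.counts_qc import equalize_depth_matrix
from peakdiff.diffacc import (
    DifferentialCallSettings,
    estimate_dispersions,
    nb_wald_test,
    select_differential,
    size_factors,
)
from peakdiff.pipeline import map_counts_to_rps

DATA = Path("results/dataset")
OUT = Path("results")
ALPHA = {"atac": 0.2, "dnase": 0.1}


def main() -> None:
    truth = io.read_json(DATA / "ground_truth.json")
    master = io.read_bed(DATA / "master_peaks.bed")
    rows = []
    for assay in ("atac", "dnase"):
        counts = io.read_count_matrix(DATA / f"counts_{assay}.tsv")
        rps = io.read_bed(OUT / f"rps_{assay}.bed")
        rps_counts, mapping = map_counts_to_rps(counts, master, rps)
        truth_ids = {mapping[m] for m in truth["differential_peak_ids"]
                     if m in mapping}
        eq = equalize_depth_matrix(rps_counts, seed=23)
        labels = np.array(["target" if "_target_" in c else "reference"
                           for c in eq.columns])
        sf = size_factors(eq)
        disp = estimate_dispersions(eq, sf, labels)
        res = nb_wald_test(eq, labels, sf, disp)
        res.to_csv(OUT / f"differential_{assay}.tsv", sep="\t")
        diff = select_differential(
            res, DifferentialCallSettings(ALPHA[assay], "enriched-in-target"), rps
        )
        io.write_bed(diff, OUT / f"differential_{assay}.bed")
        called = {iv.id for iv in diff}
        tp = len(called & truth_ids)
        rows.append(
            {
                "assay": assay, "alpha": ALPHA[assay], "n_called": len(called),
                "n_planted": len(truth_ids),
                "recall": round(tp / len(truth_ids), 3),
                "precision": round(tp / max(len(called), 1), 3),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "differential_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        "single-assay calls at nominal thresholds recover essentially all "
        "planted peaks but carry substantial false positives — the "
        "motivation for requiring cross-assay support (next step)"
    )


if __name__ == "__main__":
    main()
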