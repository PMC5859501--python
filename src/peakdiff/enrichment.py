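"""Fisher-exact enrichment machinery.

Used for: proximity of differential peaks to differentially expressed
(DE) genes, flat functional-category enrichment with Benjamini-Hochberg
adjustment, and the expression-class / temporal-cluster comparisons of
gene sets near differential peaks.

Fold enrichment is the ratio of proportions (a/(a+b)) / (c/(c+d)), not
the odds ratio; tests are two-sided throughout so both enrichment and
depletion are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, genes_within_window
from .intervals import PeakSet

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "ExpressionProfile",
    "fisher_enrichment",
    "proximity_enrichment",
    "category_enrichment",
    "assign_temporal_cluster",
    "assign_expression_class",
    "class_enrichment",
    "EXPRESSION_CLASS_BINS",
    "TEMPORAL_CLUSTER_WINDOWS",
]

# FPKM (at 24 hpf) class bins, half-open on the left edge of each bin
EXPRESSION_CLASS_BINS = {
    "high": (100.0, float("inf")),
    "medium": (40.0, 100.0),
    "low": (15.0, 40.0),
    "very_low": (0.0, 15.0),
}

# temporal clusters by argmax expression time (hours post-fertilization):
# cluster 1 peaks earliest (0-10 hpf), cluster 4 at 18-24, cluster 3 at
# 24-40, cluster 2 latest (40-72); (10, 18) hpf is unassigned
TEMPORAL_CLUSTER_WINDOWS = {
    1: (0.0, 10.0),
    4: (18.0, 24.0),
    3: (24.0, 40.0),
    2: (40.0, 72.0),
}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: differential / non-differential; columns: with-property /
    without-property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def margins_positive(self) -> bool:
        return (self.a + self.b) > 0 and (self.c + self.d) > 0


@dataclass
class EnrichmentResult:
    property_name: str
    p_value: float
    fold_enrichment: float
    direction: str  # enriched | depleted | none
    table: ContingencyTable2x2 | None = None
    adjusted_p: float | None = None


@dataclass
class ExpressionProfile:
    gene_id: str
    fpkm_24hpf: float
    timecourse: dict[float, float] = field(default_factory=dict)

    @property
    def temporal_cluster(self) -> int | None:
        return assign_temporal_cluster(self)

    @property
    def expression_class(self) -> str:
        return assign_expression_class(self.fpkm_24hpf)


def fisher_enrichment(
    table: ContingencyTable2x2, name: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher exact test with ratio-of-proportions fold.

    A zero row margin leaves both p and fold undefined (NaN)."""
    if not table.margins_positive:
        return EnrichmentResult(name, float("nan"), float("nan"), "none", table)
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    p_diff = table.a / (table.a + table.b)
    p_non = table.c / (table.c + table.d)
    fold = p_diff / p_non if p_non > 0 else float("inf")
    direction = "enriched" if fold > 1 else ("depleted" if fold < 1 else "none")
    return EnrichmentResult(name, float(p), float(fold), direction, table)


def proximity_enrichment(
    diff_peaks: PeakSet,
    all_peaks: PeakSet,
    genes: Sequence[GeneModel],
    de_gene_ids: set[str],
    window_bp: int = 10_000,
) -> EnrichmentResult:
    """Are differential peaks more often within 10 kb of DE genes than
    non-differential peaks?  Builds the 2x2 table and tests it."""
    if len(diff_peaks) == 0:
        raise ValueError("proximity_enrichment: empty differential peak set")
    diff_keys = {(iv.scaffold, iv.start, iv.end) for iv in diff_peaks}
    de_genes = [g for g in genes if g.gene_id in de_gene_ids]
    a = b = c = d = 0
    for iv in all_peaks:
        near = bool(genes_within_window(iv, de_genes, window_bp))
        if (iv.scaffold, iv.start, iv.end) in diff_keys:
            a, b = a + int(near), b + int(not near)
        else:
            c, d = c + int(near), d + int(not near)
    return fisher_enrichment(
        ContingencyTable2x2(a, b, c, d), name=f"within_{window_bp}bp_of_DE_gene"
    )


def category_enrichment(
    genes_near_diff: set[str],
    genes_near_nondiff: set[str],
    category_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Per-category Fisher tests with BH adjustment.

    ``category_map`` assigns each gene zero or more flat category
    labels; genes in several categories count once per category.
    """
    universe = {c for cats in category_map.values() for c in cats}
    if not universe:
        raise ValueError("category_enrichment: empty category universe")
    n_diff, n_non = len(genes_near_diff), len(genes_near_nondiff)
    results = []
    for cat in sorted(universe):
        a = sum(1 for g in genes_near_diff if cat in category_map.get(g, ()))
        c = sum(1 for g in genes_near_nondiff if cat in category_map.get(g, ()))
        results.append(
            fisher_enrichment(
                ContingencyTable2x2(a, n_diff - a, c, n_non - c), name=cat
            )
        )
    ps = [r.p_value for r in results]
    finite = np.isfinite(ps)
    adj = np.full(len(ps), np.nan)
    if finite.any():
        adj[finite] = multipletests(np.asarray(ps)[finite], method="fdr_bh")[1]
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    return results


def assign_temporal_cluster(profile: ExpressionProfile) -> int | None:
    """Cluster by the time of maximal expression; ties go to the
    earliest time; an argmax in the (10, 18) hpf gap is unassigned."""
    if not profile.timecourse:
        raise ValueError("assign_temporal_cluster: empty timecourse")
    times = sorted(profile.timecourse)
    best_t = max(times, key=lambda t: (profile.timecourse[t], -t))
    for cluster, (lo, hi) in TEMPORAL_CLUSTER_WINDOWS.items():
        # clusters 1 and 2 are closed ([0,10] and [40,72]); the (10,18)
        # gap stays unassigned, so 4 and 3 are half-open on the right
        if lo <= best_t < hi or (cluster in (1, 2) and best_t == hi):
            return cluster
    return None


def assign_expression_class(fpkm_24hpf: float) -> str:
    """Expression class from FPKM in the target cells at 24 hpf:
    [100, inf) high, [40, 100) medium, [15, 40) low, [0, 15) very_low."""
    if fpkm_24hpf < 0:
        raise ValueError("FPKM must be >= 0")
    for cls, (lo, hi) in EXPRESSION_CLASS_BINS.items():
        if lo <= fpkm_24hpf < hi:
            return cls
    raise AssertionError("unreachable: bins cover [0, inf)")


def class_enrichment(
    gene_subset: set[str],
    universe_labels: Mapping[str, str],
) -> list[EnrichmentResult]:
    """Per-label Fisher test of a gene subset against the rest of the
    labeled universe (labels are expression classes or temporal
    clusters)."""
    if not gene_subset:
        raise ValueError("class_enrichment: empty gene subset")
    subset = {g for g in gene_subset if g in universe_labels}
    rest = set(universe_labels) - subset
    results = []
    for label in sorted({str(v) for v in universe_labels.values()}):
        a = sum(1 for g in subset if str(universe_labels[g]) == label)
        c = sum(1 for g in rest if str(universe_labels[g]) == label)
        results.append(
            fisher_enrichment(
                ContingencyTable2x2(a, len(subset) - a, c, len(rest) - c),
                name=label,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table or ContingencyTable2x2(0, 0, 0, 0)
        rows.append(
            {
                "property": r.property_name,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "fold_enrichment": r.fold_enrichment,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
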