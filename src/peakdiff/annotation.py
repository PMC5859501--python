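"""Peak-to-gene annotation.

Each accessibility peak is classified relative to its *closest* gene
into one of five location categories, evaluated strand-aware in the
gene's orientation ("upstream of the 5' end of the first exon" lies
rightward of the largest coordinate for a minus-strand gene):

* ``Promoter`` — the peak's 3' end is within 1 kb upstream of the 5'
  end of the first exon (a peak straddling the gene 5' boundary counts:
  it covers the promoter region).
* ``WithinGeneBody`` — the peak's 5' end lies within the gene span
  (subcategory ``exon`` or ``intron`` by where the 5' end falls).
* ``Upstream`` — the peak's 3' end is 1–10 kb upstream of the first
  exon's 5' end.
* ``Downstream`` — the peak's 5' end is within 10 kb downstream of,
  and not overlapping, the 3' end of the last exon.
* ``Distal`` — no portion of the peak is within 10 kb of any gene.

Precedence when several rules could fire: Promoter > WithinGeneBody >
Upstream > Downstream > Distal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "classify_peak_location",
    "nearest_gene",
    "genes_within_window",
    "annotate_peaks",
    "location_distribution",
    "CATEGORIES",
]

CATEGORIES = ("Upstream", "Promoter", "WithinGeneBody", "Downstream", "Distal")

PROMOTER_BP = 1_000
WINDOW_BP = 10_000


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded span with ordered disjoint exons.

    Transcript isoforms are collapsed to a single model; the span runs
    from the first exon's start to the last exon's end (0-based
    half-open, like all internal coordinates).
    """

    gene_id: str
    scaffold: str
    strand: Literal["+", "-"]
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.start, self.end, self.gene_id)

    def gap_to(self, peak: GenomicInterval) -> int | None:
        return self.span.gap_to(peak)


@dataclass
class PeakAnnotation:
    peak_id: str
    category: str
    subcategory: str  # intron | exon | none
    nearest_gene: str | None
    distance_bp: int
    genes_within_10kb: set[str] = field(default_factory=set)


def _position_in_exon(pos: int, gene: GeneModel) -> bool:
    return any(e.start <= pos < e.end for e in gene.exons)


def classify_peak_location(
    peak: GenomicInterval,
    gene: GeneModel,
    *,
    promoter_bp: int = PROMOTER_BP,
    window_bp: int = WINDOW_BP,
) -> tuple[str, str]:
    """Classify a peak's location relative to one gene.

    Returns ``(category, subcategory)``.  Different scaffolds are Distal
    by definition.  See the module docstring for the rules and their
    precedence.
    """
    if peak.scaffold != gene.scaffold:
        return "Distal", "none"

    if gene.strand == "+":
        peak5, peak3 = peak.start, peak.end  # in gene orientation
        up_gap = gene.start - peak3  # >=0: peak 3' end upstream of first exon
        down_gap = peak.start - gene.end  # >=0: peak 5' end downstream of last exon
        peak5_upstream = peak.start < gene.start
        body_pos = peak.start
    else:
        peak5, peak3 = peak.end, peak.start
        up_gap = peak3 - gene.end
        down_gap = gene.start - peak.end
        peak5_upstream = peak.end > gene.end
        body_pos = peak.end - 1  # last covered base = gene-oriented 5' end

    # Promoter: 3' end within 1 kb upstream; a peak extending across the
    # gene 5' boundary (up_gap < 0 with its 5' end still upstream) is kept
    # in this class — it covers the promoter region.
    if peak5_upstream and up_gap <= promoter_bp:
        return "Promoter", "none"
    if gene.start <= body_pos < gene.end:
        sub = "exon" if _position_in_exon(body_pos, gene) else "intron"
        return "WithinGeneBody", sub
    if peak5_upstream and promoter_bp < up_gap <= window_bp:
        return "Upstream", "none"
    if 0 <= down_gap <= window_bp:
        return "Downstream", "none"
    return "Distal", "none"


def nearest_gene(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str, int]:
    """Closest gene by gap between the peak and the gene span (0 when
    overlapping); ties broken by lexicographically smaller gene id.
    Genes on other scaffolds are infinitely far."""
    if not genes:
        raise ValueError("nearest_gene: empty gene set")
    best: tuple[float, str] = (float("inf"), "")
    for g in genes:
        gap = g.gap_to(peak)
        if gap is None:
            continue
        if (gap, g.gene_id) < best:
            best = (gap, g.gene_id)
    if best[1] == "":
        # no gene shares a scaffold with the peak
        return min(g.gene_id for g in genes), -1
    return best[1], int(best[0])


def genes_within_window(
    peak: GenomicInterval,
    genes: Iterable[GeneModel],
    window_bp: int = WINDOW_BP,
) -> set[str]:
    """Gene ids whose span is within ``window_bp`` of the peak.

    The boundary is inclusive: a gap of exactly ``window_bp`` counts;
    overlap (gap 0) counts.
    """
    out = set()
    for g in genes:
        gap = g.gap_to(peak)
        if gap is not None and gap <= window_bp:
            out.add(g.gene_id)
    return out


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    *,
    window_bp: int = WINDOW_BP,
) -> list[PeakAnnotation]:
    """Full annotation: nearest gene, location category against that
    gene, and the 10-kb gene-proximity set, per peak."""
    genes_by_id = {g.gene_id: g for g in genes}
    out = []
    for i, peak in enumerate(peaks):
        pid = peak.id or f"peak_{i}"
        gid, dist = nearest_gene(peak, genes)
        near = genes_within_window(peak, genes, window_bp)
        if dist < 0 or dist > window_bp:
            # nearest gene beyond the window: Distal by the "no portion
            # within 10 kb" clause
            cat, sub = "Distal", "none"
        else:
            cat, sub = classify_peak_location(peak, genes_by_id[gid], window_bp=window_bp)
        out.append(PeakAnnotation(pid, cat, sub, gid if dist >= 0 else None, dist, near))
    return out


def location_distribution(
    peaks: PeakSet, genes: Sequence[GeneModel], *, window_bp: int = WINDOW_BP
) -> pd.DataFrame:
    """Per-category peak counts and fractions (fractions sum to 1)."""
    anns = annotate_peaks(peaks, genes, window_bp=window_bp)
    counts = {c: 0 for c in CATEGORIES}
    for a in anns:
        counts[a.category] += 1
    n = max(len(anns), 1)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / n for c in CATEGORIES],
        }
    )
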