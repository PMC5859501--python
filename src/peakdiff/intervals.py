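"""Genomic interval algebra for peak sets.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Peaks are unstranded.  The central operations are union-merge, the
fraction of a query interval covered by the union of a target set
("non-reciprocal" overlap), construction of a replicate-supported
reference peak set (RPS), and the cross-assay merge of differential
peaks from two independent accessibility assays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapCriterion",
    "overlap_fraction",
    "merge_union",
    "build_reference_peak_set",
    "cross_assay_merge",
    "genome_coverage",
    "present_in",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a scaffold; the atom of all peak algebra."""

    scaffold: str
    start: int
    end: int
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between the two intervals; 0 if they overlap or abut,
        None if on different scaffolds."""
        if self.scaffold != other.scaffold:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class PeakSet:
    """An ordered collection of intervals, sorted by (scaffold, start).

    A *merged* PeakSet is pairwise disjoint.  Internally peaks are held per
    scaffold as numpy start/end arrays so that overlap queries are
    binary searches rather than scans.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end)
        )
        self.label = label
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(i.scaffold, i.start, i.end) for i in self.intervals] == [
            (i.scaffold, i.start, i.end) for i in other.intervals
        ]

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals, label={self.label!r})"

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def scaffolds(self) -> list[str]:
        return sorted({iv.scaffold for iv in self.intervals})

    def by_scaffold(self, scaffold: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.scaffold == scaffold]

    def ids(self) -> list[str | None]:
        return [iv.id for iv in self.intervals]

    def is_disjoint(self) -> bool:
        for a, b in itertools.pairwise(self.intervals):
            if a.scaffold == b.scaffold and b.start < a.end:
                return False
        return True

    def _merged_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-scaffold (starts, ends) arrays of the merged union, cached."""
        if self._index is None:
            merged = merge_union(self)
            idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for scaf in merged.scaffolds():
                ivs = merged.by_scaffold(scaf)
                idx[scaf] = (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
            self._index = idx
        return self._index


@dataclass(frozen=True)
class OverlapCriterion:
    """How a query peak qualifies against a partner set.

    ``fraction-of-query`` demands that at least ``min_fraction`` of the
    query's own length is covered by the union of the partner set — the
    non-reciprocal criterion; ``any-overlap`` demands at least ``min_bp``
    overlapping bases (1 nt by default).
    """

    min_fraction: float = 0.75
    min_bp: int = 1
    mode: Literal["fraction-of-query", "any-overlap"] = "fraction-of-query"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        if self.mode not in ("fraction-of-query", "any-overlap"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _covered_bp(query: GenomicInterval, targets: PeakSet) -> int:
    """Bases of `query` covered by the union of `targets`."""
    idx = targets._merged_index()
    if query.scaffold not in idx:
        return 0
    starts, ends = idx[query.scaffold]
    # merged intervals are disjoint and sorted: clip each to the query
    lo = int(np.searchsorted(ends, query.start, side="right"))
    hi = int(np.searchsorted(starts, query.end, side="left"))
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], query.start)
    e = np.minimum(ends[lo:hi], query.end)
    return int(np.maximum(e - s, 0).sum())


def overlap_fraction(query: GenomicInterval, targets: PeakSet) -> float:
    """Fraction of the query's own length covered by the union of targets.

    This is the non-reciprocal overlap fraction: only the query's length
    enters the denominator.  Returns 0.0 when the query's scaffold is
    absent from the target set.
    """
    return _covered_bp(query, targets) / len(query)


def merge_union(
    intervals: Iterable[GenomicInterval] | PeakSet,
    *,
    merge_book_ended: bool = False,
    label: str = "",
) -> PeakSet:
    """Minimal disjoint interval set covering exactly the union.

    Book-ended intervals ([0,10) and [10,20)) share no base and are kept
    separate unless ``merge_book_ended`` is set.  Idempotent and
    order-invariant.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].scaffold == iv.scaffold and (
            iv.start < out[-1].end or (merge_book_ended and iv.start == out[-1].end)
        ):
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.scaffold, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.scaffold, iv.start, iv.end, iv.id))
    return PeakSet(out, label=label)


def build_reference_peak_set(
    replicates: Sequence[PeakSet],
    criterion: OverlapCriterion = OverlapCriterion(),
    *,
    pairwise_all: bool = False,
    label: str = "RPS",
) -> PeakSet:
    """Replicate-supported reference peak set (RPS).

    A peak from one replicate qualifies when the fraction of its own
    length covered by the union of the *other* replicates meets
    ``criterion.min_fraction`` (non-reciprocal).  With three or more
    replicates the default tests each peak against the pooled union of
    the others; ``pairwise_all=True`` instead requires the fraction to
    be met against every other replicate separately.  Qualifying peaks
    from all replicates are then union-merged.  The result does not
    depend on replicate order.
    """
    if len(replicates) < 2:
        raise ValueError("reference peak set construction needs >= 2 replicate peak sets")
    qualifying: list[GenomicInterval] = []
    for i, rep in enumerate(replicates):
        others = [r for j, r in enumerate(replicates) if j != i]
        if pairwise_all:
            partner_sets = others
        else:
            partner_sets = [PeakSet([iv for r in others for iv in r])]
        for peak in rep:
            if all(
                overlap_fraction(peak, partner) >= criterion.min_fraction
                for partner in partner_sets
            ):
                qualifying.append(peak)
    return merge_union(qualifying, label=label)


def cross_assay_merge(
    diff_a: PeakSet,
    diff_b: PeakSet,
    criterion: OverlapCriterion = OverlapCriterion(),
    *,
    label: str = "overlapping_differential",
) -> PeakSet:
    """Merge differential peaks supported by both assays.

    A peak from either side qualifies when >= ``min_fraction`` of its own
    sequence is covered by the other side's peaks (non-reciprocal, so a
    qualifying peak's partner need not reciprocate).  Qualifying peaks
    from both sides are pooled and union-merged.  Symmetric in (a, b);
    empty inputs yield an empty result.
    """
    qualifying = [
        p for p in diff_a if overlap_fraction(p, diff_b) >= criterion.min_fraction
    ] + [p for p in diff_b if overlap_fraction(p, diff_a) >= criterion.min_fraction]
    return merge_union(qualifying, label=label)


def genome_coverage(peaks: PeakSet, genome_size: int) -> float:
    """Fraction of the genome covered by the union of the peaks."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return merge_union(peaks).total_bp / genome_size


def present_in(
    peaks: PeakSet,
    reference: PeakSet,
    criterion: OverlapCriterion = OverlapCriterion(),
) -> list[bool]:
    """Flag, per query peak, whether it satisfies the criterion against
    the reference set (fraction-of-query or >= min_bp any-overlap)."""
    flags = []
    for peak in peaks:
        if criterion.mode == "fraction-of-query":
            flags.append(overlap_fraction(peak, reference) >= criterion.min_fraction)
        else:
            flags.append(_covered_bp(peak, reference) >= criterion.min_bp)
    return flags
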