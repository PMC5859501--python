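"""Read counting, depth equalization, FRiP, and replicate concordance.

The QC gates mirror standard accessibility-assay practice: every
library must clear a minimum fraction-of-reads-in-peaks (FRiP) of 0.4,
and replicates must be pairwise concordant (Pearson r; retained at
>= 0.9, excluded at <= 0.8 mean pairwise correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "SampleMeta",
    "QCReport",
    "count_reads_in_peaks",
    "equalize_depth_reads",
    "equalize_depth_matrix",
    "frip",
    "replicate_concordance",
    "FRIP_THRESHOLD",
    "PEARSON_RETAIN",
    "PEARSON_EXCLUDE",
]

FRIP_THRESHOLD = 0.4
PEARSON_RETAIN = 0.90
PEARSON_EXCLUDE = 0.80


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    assay: str  # atac | dnase
    condition: str  # target | reference
    replicate: int
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class QCReport:
    frip_per_sample: dict[str, float] = field(default_factory=dict)
    pearson_matrix: pd.DataFrame | None = None
    retained_samples: set[str] = field(default_factory=set)
    excluded_samples: set[str] = field(default_factory=set)


def _peak_arrays(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    grouped: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(peaks.intervals):
        grouped.setdefault(iv.scaffold, []).append((i, iv))
    by_scaf: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for scaf, items in grouped.items():
        by_scaf[scaf] = (
            np.array([iv.start for _, iv in items], dtype=np.int64),
            np.array([iv.end for _, iv in items], dtype=np.int64),
            np.array([i for i, _ in items], dtype=np.int64),
        )
    return by_scaf


def count_reads_in_peaks(reads: PeakSet, peaks: PeakSet) -> np.ndarray:
    """Count reads per peak over a disjoint peak set.

    Each read contributes to at most one peak: the peak with the
    greatest overlap, ties to the leftmost.  Reads with no overlap are
    uncounted, so the counts sum to at most the number of reads.
    """
    if not peaks.is_disjoint():
        raise ValueError("count_reads_in_peaks requires a disjoint (merged) peak set")
    counts = np.zeros(len(peaks), dtype=np.int64)
    arrays = _peak_arrays(peaks)
    for read in reads:
        if read.scaffold not in arrays:
            continue
        starts, ends, idx = arrays[read.scaffold]
        lo = int(np.searchsorted(ends, read.start, side="right"))
        hi = int(np.searchsorted(starts, read.end, side="left"))
        if hi <= lo:
            continue
        ov = np.minimum(ends[lo:hi], read.end) - np.maximum(starts[lo:hi], read.start)
        best = int(np.argmax(ov))  # argmax takes the first (leftmost) maximum
        if ov[best] > 0:
            counts[idx[lo + best]] += 1
    return counts


def equalize_depth_reads(
    read_sets: dict[str, PeakSet], seed: int
) -> dict[str, PeakSet]:
    """Subsample each read set without replacement to the minimum depth."""
    if len(read_sets) < 2:
        raise ValueError("depth equalization needs >= 2 samples")
    depths = {k: len(v) for k, v in read_sets.items()}
    if min(depths.values()) == 0:
        raise ValueError("cannot equalize a sample with zero reads")
    target = min(depths.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(read_sets):
        rs = read_sets[name]
        if len(rs) == target:
            out[name] = rs
        else:
            keep = rng.choice(len(rs), size=target, replace=False)
            out[name] = PeakSet([rs.intervals[i] for i in sorted(keep)], label=rs.label)
    return out


def equalize_depth_matrix(counts: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample count-matrix columns to the minimum column total.

    Each column is treated as its reads: sampling without replacement to
    the target depth makes every peak's retained count multivariate-
    hypergeometric.  Columns already at the target are untouched.
    """
    if counts.shape[1] < 2:
        raise ValueError("depth equalization needs >= 2 samples")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot equalize a sample with zero depth")
    target = int(totals.min())
    rng = np.random.default_rng(seed)
    out = counts.copy()
    for col in counts.columns:
        if int(totals[col]) != target:
            out[col] = rng.multivariate_hypergeometric(
                counts[col].to_numpy(dtype=np.int64), target
            )
    return out


def frip(reads: PeakSet, peaks: PeakSet) -> tuple[float, bool]:
    """Fraction of reads overlapping any peak by >= 1 bp, and the 0.4
    gate flag.  Peaks are union-merged internally, which leaves the
    value unchanged (>= 1 bp overlap with *any* peak)."""
    if len(reads) == 0:
        raise ValueError("FRiP undefined with zero reads")
    from .intervals import merge_union

    merged = merge_union(peaks)
    arrays = _peak_arrays(merged)
    reads_by_scaf: dict[str, list[GenomicInterval]] = {}
    for read in reads:
        reads_by_scaf.setdefault(read.scaffold, []).append(read)
    n_in = 0
    for scaf, rs in reads_by_scaf.items():
        if scaf not in arrays:
            continue
        starts, ends, _ = arrays[scaf]
        r_start = np.array([r.start for r in rs], dtype=np.int64)
        r_end = np.array([r.end for r in rs], dtype=np.int64)
        # with disjoint sorted peaks a read overlaps iff the first peak
        # ending after its start begins before its end
        j = np.searchsorted(ends, r_start, side="right")
        ok = j < len(starts)
        hit = np.zeros(len(rs), dtype=bool)
        hit[ok] = starts[j[ok]] < r_end[ok]
        n_in += int(hit.sum())
    value = n_in / len(reads)
    return value, value >= FRIP_THRESHOLD


def replicate_concordance(
    counts: pd.DataFrame,
    samples: list[SampleMeta] | None = None,
    *,
    log_transform: bool = True,
    retain_threshold: float = PEARSON_RETAIN,
    exclude_threshold: float = PEARSON_EXCLUDE,
) -> QCReport:
    """Pairwise Pearson concordance over per-peak counts.

    Counts are log1p-transformed before the correlation unless
    ``log_transform`` is False (raw counts are heavy-tailed; the
    transform stabilizes r).  A replicate is excluded when its mean
    pairwise correlation with same-condition replicates falls at or
    below ``exclude_threshold``; a pair with a constant column has an
    undefined correlation, reported as NaN and ignored in the mean.
    """
    x = counts.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(x)
    cols = list(counts.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    # a constant column has no defined correlation with anything
    constant = np.ptp(x, axis=0) == 0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    pearson = pd.DataFrame(r, index=cols, columns=cols)

    groups: dict[str, list[str]] = {}
    if samples is not None:
        by_id = {s.sample_id: s for s in samples}
        for c in cols:
            key = f"{by_id[c].assay}:{by_id[c].condition}" if c in by_id else "all"
            groups.setdefault(key, []).append(c)
    else:
        groups["all"] = cols

    retained, excluded = set(), set()
    for members in groups.values():
        if len(members) < 2:
            retained.update(members)
            continue
        # drop the least-concordant replicate until the survivors are
        # mutually concordant, so one bad library cannot drag down the
        # mean correlation of its good peers
        alive = list(members)
        while len(alive) >= 2:
            means = {}
            for c in alive:
                rs = [pearson.loc[c, o] for o in alive if o != c]
                rs = [v for v in rs if np.isfinite(v)]
                means[c] = float(np.mean(rs)) if rs else np.nan
            worst = min(
                (c for c in alive if np.isfinite(means[c])),
                key=lambda c: means[c],
                default=None,
            )
            if worst is None or means[worst] > exclude_threshold:
                break
            excluded.add(worst)
            alive.remove(worst)
        retained.update(alive)
    return QCReport(pearson_matrix=pearson, retained_samples=retained,
                    excluded_samples=excluded)
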