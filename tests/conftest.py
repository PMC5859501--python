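import numpy as np
import pytest

from peakdiff.intervals import GenomicInterval, PeakSet
from peakdiff.simulate import SimulationConfig, simulate_all


def random_intervals(rng, n, scaffolds=("s1", "s2"), span=2_000, max_len=120):
    """Random small intervals for oracle comparisons."""
    out = []
    for _ in range(n):
        scaf = scaffolds[rng.integers(len(scaffolds))]
        start = int(rng.integers(0, span - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(scaf, start, min(start + length, span)))
    return out


def bitmap_union(intervals, scaffolds=("s1", "s2"), span=2_000):
    """Per-base boolean coverage bitmap, the brute-force oracle for all
    union/coverage/overlap computations."""
    maps = {s: np.zeros(span, dtype=bool) for s in scaffolds}
    for iv in intervals:
        maps[iv.scaffold][iv.start : iv.end] = True
    return maps


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_scaffolds=2,
        scaffold_length=300_000,
        n_genes=40,
        n_de_genes=10,
        n_peaks=120,
        frac_differential=0.15,
        mean_depth=120.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)
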