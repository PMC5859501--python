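"""Synthetic chromatin-accessibility data with planted ground truth.

Generates a toy multi-scaffold genome, non-overlapping gene models with
expression profiles and a designated differentially-expressed (DE)
subset, replicate peak calls (boundary-jittered copies of a master peak
landscape), negative-binomial count matrices with planted log2 fold
changes for two assay designs, optional read intervals for
FRiP/counting tests, and peak sequences carrying a planted consensus
motif — everything a downstream differential-accessibility pipeline
consumes, with a manifest recording the truth.

Two assay designs are emulated:

* ``atac`` — cell-sorted: target cells vs all other cells; planted
  peaks are more accessible in the target cells.
* ``dnase`` — whole-embryo control vs lineage-ablated embryos; planted
  peaks carry signal in the control and background-only counts in the
  ablated condition.

Both reduce to the same count model: mu_ij = mean_depth * b_i * s_j *
2^(x_j * planted_log2fc) for planted peaks (x_j = 1 in the accessible
condition) and mu_ij = mean_depth * b_i * s_j otherwise, with NB
dispersion alpha.  The per-peak abundance factor b_i (lognormal, shared
across samples) gives replicates the strong per-peak correlation real
libraries show; without it between-replicate Pearson r would be ~0 and
no concordance gate could ever pass.

Every output is a pure function of the ``SimulationConfig`` (seed
included); identical configs reproduce identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .counts_qc import SampleMeta
from .intervals import GenomicInterval, PeakSet
from .motifs import PWM

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_genome",
    "generate_genes",
    "generate_peak_landscape",
    "generate_counts",
    "emit_reads",
    "plant_motifs",
    "default_pwm_set",
    "simulate_all",
    "corrupt_replicate",
]

ASSAYS = ("atac", "dnase")
CONDITIONS = ("target", "reference")
TIMEPOINTS = (0.0, 6.0, 10.0, 12.0, 18.0, 21.0, 24.0, 30.0, 36.0, 40.0,
              48.0, 56.0, 64.0, 72.0)
CATEGORY_LABELS = (
    "biomineralization", "metalloprotease", "signaling",
    "transcription_factor", "metabolism", "transport",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults give a ~3 Mb toy genome with 1000 peaks of ~600 bp
    (≈20% genome coverage), 8% of peaks carrying a planted log2 fold
    change of 2 within 10 kb of DE genes, NB dispersion 0.05 and a mean
    depth of 200 reads per peak — small enough to run in seconds,
    structured like the data the pipeline is built for.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 600_000
    n_genes: int = 300
    n_de_genes: int = 60
    n_peaks: int = 1000
    frac_differential: float = 0.08
    planted_log2fc: float = 2.0
    dispersion: float = 0.05
    mean_depth: float = 200.0
    replicate_jitter_bp: int = 25
    n_replicates_per_condition: int = 3
    motif_plant_rate: float = 0.6
    de_window: int = 10_000
    gc_fraction: float = 0.5
    peak_width_mean: float = 600.0
    peak_width_sd: float = 150.0
    min_peak_width: int = 200
    baseline_sigma: float = 1.0  # lognormal sigma of per-peak abundance b_i
    gene_width_range: tuple[int, int] = (1_500, 5_000)
    read_length: int = 50
    target_frip: float = 0.635  # sets the background read rate

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        if not 0.0 < self.frac_differential < 1.0:
            raise ValueError("frac_differential must be in (0, 1)")
        for name in ("n_scaffolds", "scaffold_length", "n_genes", "n_peaks",
                     "min_peak_width", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.mean_depth <= 0:
            raise ValueError("dispersion must be >= 0 and mean_depth > 0")
        if not 0.0 <= self.motif_plant_rate <= 1.0:
            raise ValueError("motif_plant_rate must be in [0, 1]")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.replicate_jitter_bp * 2 >= self.min_peak_width:
            raise ValueError("replicate jitter must be < half the minimum peak width")

    @property
    def genome_size(self) -> int:
        return self.n_scaffolds * self.scaffold_length

    @property
    def n_differential(self) -> int:
        return int(round(self.n_peaks * self.frac_differential))


@dataclass
class GroundTruth:
    differential_peak_ids: set[str] = field(default_factory=set)
    de_gene_ids: set[str] = field(default_factory=set)
    planted_log2fc_per_peak: dict[str, float] = field(default_factory=dict)
    motif_planted_peak_ids: set[str] = field(default_factory=set)
    size_factors: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    sizes: dict[str, int]
    genes: list[GeneModel]
    expression: pd.DataFrame  # gene_id, fpkm_24hpf, is_de, t<hpf> columns
    categories: dict[str, list[str]]
    master_peaks: PeakSet
    replicate_peaks: dict[tuple[str, str, int], PeakSet]
    counts: dict[str, pd.DataFrame]  # assay -> peaks x samples
    samples: dict[str, list[SampleMeta]]
    pwms: list[PWM]
    truth: GroundTruth

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_genes": len(self.genes),
            "n_peaks": len(self.master_peaks),
            "differential_peak_ids": sorted(self.truth.differential_peak_ids),
            "de_gene_ids": sorted(self.truth.de_gene_ids),
            "motif_planted_peak_ids": sorted(self.truth.motif_planted_peak_ids),
            "planted_log2fc_per_peak": self.truth.planted_log2fc_per_peak,
            "size_factors": self.truth.size_factors,
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], dict[str, int]]:
    """Random scaffold sequences with the configured GC fraction."""
    rng = _rng(config, 1)
    gc, at = config.gc_fraction / 2, (1 - config.gc_fraction) / 2
    probs = np.array([at, gc, gc, at])  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome, sizes = {}, {}
    for i in range(config.n_scaffolds):
        name = f"scaffold_{i + 1}"
        draws = rng.choice(4, size=config.scaffold_length, p=probs)
        genome[name] = alphabet[draws].tobytes().decode("ascii")
        sizes[name] = config.scaffold_length
    return genome, sizes


class _Occupancy:
    """Per-scaffold sorted occupied intervals for disjoint placement."""

    def __init__(self, scaffolds: Sequence[str]):
        self._by_scaf: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}

    def fits(self, scaffold: str, start: int, end: int) -> bool:
        import bisect

        ivs = self._by_scaf[scaffold]
        i = bisect.bisect_left(ivs, (start, start))
        if i > 0 and ivs[i - 1][1] > start:
            return False
        if i < len(ivs) and ivs[i][0] < end:
            return False
        return True

    def add(self, scaffold: str, start: int, end: int) -> None:
        import bisect

        bisect.insort(self._by_scaf[scaffold], (start, end))


def generate_genes(
    config: SimulationConfig, sizes: dict[str, int]
) -> tuple[list[GeneModel], pd.DataFrame, dict[str, list[str]], GroundTruth]:
    """Place non-overlapping gene models; label a DE subset; draw
    expression profiles (FPKM at 24 hpf plus a temporal bump whose peak
    time falls in one of the four cluster windows) and flat functional
    categories, with DE genes biased toward biomineralization."""
    rng = _rng(config, 2)
    scaffolds = sorted(sizes)
    occ = _Occupancy(scaffolds)
    genes: list[GeneModel] = []
    lo_w, hi_w = config.gene_width_range
    attempts = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > 200 * config.n_genes:
            raise ValueError(
                f"genome too small to place {config.n_genes} disjoint genes"
            )
        scaf = scaffolds[rng.integers(len(scaffolds))]
        width = int(rng.integers(lo_w, hi_w + 1))
        if width >= sizes[scaf]:
            continue
        start = int(rng.integers(0, sizes[scaf] - width))
        if not occ.fits(scaf, start, start + width):
            continue
        occ.add(scaf, start, start + width)
        gid = f"gene_{len(genes) + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(np.arange(1, width), size=2 * n_exons - 2,
                                  replace=False)) if n_exons > 1 else np.array([])
        bounds = np.concatenate([[0], cuts, [width]])
        exons = tuple(
            GenomicInterval(scaf, start + int(bounds[2 * k]),
                            start + int(bounds[2 * k + 1]))
            for k in range(n_exons)
            if bounds[2 * k] < bounds[2 * k + 1]
        )
        genes.append(GeneModel(gid, scaf, strand, exons))

    de_ids = set(
        f"gene_{i + 1:04d}"
        for i in rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    )

    # expression: lognormal FPKM spanning the four class bins; temporal
    # bump centered in one of the four cluster windows
    cluster_windows = {1: (0.0, 10.0), 4: (18.0, 24.0), 3: (24.0, 40.0),
                       2: (40.0, 72.0)}
    rows = []
    for g in genes:
        fpkm = float(np.minimum(rng.lognormal(np.log(40.0), 1.5), 2512.0))
        cluster = int(rng.integers(1, 5))
        lo_t, hi_t = cluster_windows[cluster]
        center = float(rng.uniform(lo_t, hi_t))
        t = np.array(TIMEPOINTS)
        profile = np.exp(-0.5 * ((t - center) / 8.0) ** 2) * fpkm + 0.01
        rows.append(
            {"gene_id": g.gene_id, "fpkm_24hpf": fpkm, "is_de": g.gene_id in de_ids,
             "assigned_cluster": cluster,
             **{f"t{tp:g}": float(v) for tp, v in zip(TIMEPOINTS, profile)}}
        )
    expression = pd.DataFrame(rows).set_index("gene_id")

    categories: dict[str, list[str]] = {}
    for g in genes:
        cats = []
        if g.gene_id in de_ids:
            if rng.random() < 0.35:
                cats.append("biomineralization")
            if rng.random() < 0.15:
                cats.append("metalloprotease")
        if not cats and rng.random() < 0.5:
            cats.append(str(rng.choice(CATEGORY_LABELS[2:])))
        categories[g.gene_id] = cats

    truth = GroundTruth(de_gene_ids=de_ids)
    return genes, expression, categories, truth


def generate_peak_landscape(
    config: SimulationConfig,
    sizes: dict[str, int],
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    expression: pd.DataFrame | None = None,
) -> tuple[PeakSet, dict[tuple[str, str, int], PeakSet]]:
    """Master peak landscape plus jittered per-sample peak calls.

    Planted differential peaks are placed within ``de_window`` of DE
    gene spans (weighted toward high-FPKM DE genes: strongly expressed
    genes attract regulatory activity); the rest are uniform.  All
    peaks are pairwise disjoint.  Each replicate's call set is the
    master with boundaries independently jittered by up to
    ``replicate_jitter_bp``.
    """
    rng = _rng(config, 3)
    scaffolds = sorted(sizes)
    occ = _Occupancy(scaffolds)
    de_genes = [g for g in genes if g.gene_id in truth.de_gene_ids]
    if config.n_differential > 0 and not de_genes:
        raise ValueError("cannot plant differential peaks without DE genes")

    weights = None
    if expression is not None and de_genes:
        w = np.array([expression.loc[g.gene_id, "fpkm_24hpf"] for g in de_genes])
        weights = w / w.sum()

    def draw_width() -> int:
        return max(config.min_peak_width,
                   int(rng.normal(config.peak_width_mean, config.peak_width_sd)))

    intervals: list[GenomicInterval] = []
    n_diff = config.n_differential
    attempts = 0
    while len(intervals) < config.n_peaks:
        attempts += 1
        if attempts > 500 * config.n_peaks:
            raise ValueError("genome too crowded to place the requested peaks")
        width = draw_width()
        if len(intervals) < n_diff:
            # within de_window of a DE gene span
            idx = rng.choice(len(de_genes), p=weights)
            g = de_genes[idx]
            lo = max(0, g.start - config.de_window - width)
            hi = min(sizes[g.scaffold] - width, g.end + config.de_window)
            if hi <= lo:
                continue
            scaf = g.scaffold
            start = int(rng.integers(lo, hi))
        else:
            scaf = scaffolds[rng.integers(len(scaffolds))]
            if width >= sizes[scaf]:
                continue
            start = int(rng.integers(0, sizes[scaf] - width))
        if not occ.fits(scaf, start, start + width):
            continue
        occ.add(scaf, start, start + width)
        intervals.append(GenomicInterval(scaf, start, start + width))

    # stable ids in coordinate order
    ordered = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start))
    id_of = {}
    final = []
    for i, iv in enumerate(ordered):
        pid = f"peak_{i + 1:05d}"
        id_of[(iv.scaffold, iv.start)] = pid
        final.append(GenomicInterval(iv.scaffold, iv.start, iv.end, pid))
    master = PeakSet(final, label="master")

    for iv in intervals[:n_diff]:
        pid = id_of[(iv.scaffold, iv.start)]
        truth.differential_peak_ids.add(pid)
        truth.planted_log2fc_per_peak[pid] = config.planted_log2fc

    replicate_peaks: dict[tuple[str, str, int], PeakSet] = {}
    j = config.replicate_jitter_bp
    for assay in ASSAYS:
        for condition in CONDITIONS:
            for rep in range(1, config.n_replicates_per_condition + 1):
                if j == 0:
                    replicate_peaks[(assay, condition, rep)] = PeakSet(
                        master.intervals, label=f"{assay}_{condition}_r{rep}"
                    )
                    continue
                jittered = []
                for iv in master:
                    ds = int(rng.integers(-j, j + 1))
                    de = int(rng.integers(-j, j + 1))
                    s = max(0, iv.start + ds)
                    e = min(sizes[iv.scaffold], iv.end + de)
                    if e <= s:  # cannot happen while jitter < width/2
                        s, e = iv.start, iv.end
                    jittered.append(GenomicInterval(iv.scaffold, s, e, iv.id))
                replicate_peaks[(assay, condition, rep)] = PeakSet(
                    jittered, label=f"{assay}_{condition}_r{rep}"
                )
    return master, replicate_peaks


def generate_counts(
    config: SimulationConfig,
    peaks: PeakSet,
    truth: GroundTruth,
    assay: str,
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """NB count matrix for one assay (peaks x samples).

    mu_ij = mean_depth * b_i * s_j * 2^(x_j * lfc_i) with x_j = 1 in
    the accessible (target) condition; b_i lognormal with unit median;
    s_j uniform depth factors recorded in the ground truth.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    rng = _rng(config, 4 + ASSAYS.index(assay))
    pids = [iv.id for iv in peaks]
    P = len(pids)
    lfc = np.array([truth.planted_log2fc_per_peak.get(p, 0.0) for p in pids])
    b = rng.lognormal(0.0, config.baseline_sigma, size=P)

    samples, cols = [], {}
    for condition in CONDITIONS:
        x = 1.0 if condition == "target" else 0.0
        for rep in range(1, config.n_replicates_per_condition + 1):
            sid = f"{assay}_{condition}_r{rep}"
            s_j = float(rng.uniform(0.7, 1.3))
            truth.size_factors[sid] = s_j
            mu = config.mean_depth * b * s_j * np.power(2.0, x * lfc)
            if config.dispersion < 1e-8:
                y = rng.poisson(mu)
            else:
                n_param = 1.0 / config.dispersion
                y = rng.negative_binomial(n_param, n_param / (n_param + mu))
            cols[sid] = y
            samples.append(
                SampleMeta(sid, assay, condition, rep, depth=int(y.sum()))
            )
    counts = pd.DataFrame(cols, index=pd.Index(pids, name="peak_id"))
    return counts, samples


def emit_reads(
    config: SimulationConfig,
    peaks: PeakSet,
    counts: pd.Series | np.ndarray,
    sizes: dict[str, int],
    seed: int,
) -> PeakSet:
    """Read intervals realizing a count column: each peak's reads are
    placed uniformly inside it, plus genome-wide background reads at a
    rate set so the expected FRiP matches ``config.target_frip``."""
    rng = np.random.default_rng(seed)
    y = np.asarray(counts, dtype=int)
    rl = config.read_length
    reads = []
    for iv, c in zip(peaks, y):
        if c <= 0:
            continue
        span = max(1, len(iv) - rl)
        starts = iv.start + rng.integers(0, span, size=c)
        for s in starts:
            reads.append(GenomicInterval(iv.scaffold, int(s), int(s) + rl))
    n_in = len(reads)
    # background reads also land in peaks at the coverage rate; solve
    # (n_in + cov*n_bg)/(n_in + n_bg) = target_frip for n_bg
    cov = min(sum(len(iv) for iv in peaks) / sum(sizes.values()), 0.99)
    f = max(config.target_frip, cov + 1e-6)
    n_bg = int(round(n_in * (1.0 - f) / (f - cov)))
    scaffolds = sorted(sizes)
    for _ in range(n_bg):
        scaf = scaffolds[rng.integers(len(scaffolds))]
        s = int(rng.integers(0, sizes[scaf] - rl))
        reads.append(GenomicInterval(scaf, s, s + rl))
    return PeakSet(reads, label="reads")


def default_pwm_set() -> list[PWM]:
    """A planted TF motif plus five decoys, built from consensus
    strings (0.88 on the consensus base)."""
    consensi = {
        "Ets1": "ACAGGAAGTG",     # planted: GGAA-core ETS-family site
        "Alx1": "TAATTGAATTA",
        "HesC": "CACGCGTGTA",
        "Tbr": "TCACACCTAG",
        "Erg": "CCGGATGTAC",
        "FoxB": "TGTTTACTTTG",
    }
    pwms = []
    for name, cons in consensi.items():
        mat = np.full((len(cons), 4), 0.04)
        for i, base in enumerate(cons):
            mat[i, "ACGT".index(base)] = 0.88
        pwms.append(PWM(name, mat))
    return pwms


def plant_motifs(
    config: SimulationConfig,
    genome: dict[str, str],
    peaks: PeakSet,
    pwms: Sequence[PWM],
    truth: GroundTruth,
) -> dict[str, str]:
    """Write the first PWM's consensus at a random offset inside each
    differential peak with probability ``motif_plant_rate``; other
    peaks and the rest of the genome are untouched."""
    rng = _rng(config, 10)
    planted = pwms[0]
    site = planted.consensus
    mutable = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for iv in peaks:
        if iv.id not in truth.differential_peak_ids:
            continue
        if rng.random() >= config.motif_plant_rate:
            continue
        if len(site) >= len(iv):
            warnings.warn(
                f"PWM {planted.motif_id} wider than peak {iv.id}; skipped",
                stacklevel=2,
            )
            continue
        off = int(rng.integers(0, len(iv) - len(site)))
        mutable[iv.scaffold][iv.start + off : iv.start + off + len(site)] = (
            site.encode("ascii")
        )
        truth.motif_planted_peak_ids.add(iv.id)
    return {name: bs.decode("ascii") for name, bs in mutable.items()}


def peak_sequences(genome: dict[str, str], peaks: PeakSet) -> dict[str, str]:
    """Extract each peak's sequence from the genome, keyed by peak id."""
    out = {}
    for i, iv in enumerate(peaks):
        out[iv.id or f"peak_{i}"] = genome[iv.scaffold][iv.start : iv.end]
    return out


def corrupt_replicate(counts: pd.DataFrame, column: str, seed: int) -> pd.DataFrame:
    """Permute one sample's counts across peaks — a discordant
    replicate that the concordance gate should exclude."""
    rng = np.random.default_rng(seed)
    out = counts.copy()
    out[column] = rng.permutation(out[column].to_numpy())
    return out


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generation stage in order and bundle the results."""
    genome, sizes = generate_genome(config)
    genes, expression, categories, truth = generate_genes(config, sizes)
    master, replicate_peaks = generate_peak_landscape(
        config, sizes, genes, truth, expression
    )
    counts, samples = {}, {}
    for assay in ASSAYS:
        counts[assay], samples[assay] = generate_counts(config, master, truth, assay)
    pwms = default_pwm_set()
    genome = plant_motifs(config, genome, master, pwms, truth)
    return SimulatedDataset(
        config=config, genome=genome, sizes=sizes, genes=genes,
        expression=expression, categories=categories, master_peaks=master,
        replicate_peaks=replicate_peaks, counts=counts, samples=samples,
        pwms=pwms, truth=truth,
    )
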