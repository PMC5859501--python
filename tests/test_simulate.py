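"""The synthetic-data generator: determinism, placement invariants, the
planted count model, and motif planting."""

import numpy as np
import pytest

from peakdiff.intervals import GenomicInterval, PeakSet
from peakdiff.simulate import (
    GroundTruth,
    SimulationConfig,
    default_pwm_set,
    emit_reads,
    generate_counts,
    generate_genes,
    generate_genome,
    generate_peak_landscape,
    plant_motifs,
    simulate_all,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_de_genes": 500, "n_genes": 100},
            {"frac_differential": 0.0},
            {"frac_differential": 1.0},
            {"scaffold_length": 0},
            {"dispersion": -0.1},
            {"motif_plant_rate": 1.5},
            {"replicate_jitter_bp": 150, "min_peak_width": 200},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenerateGenome:
    def test_total_size(self):
        cfg = SimulationConfig(n_scaffolds=2, scaffold_length=100_000)
        genome, sizes = generate_genome(cfg)
        assert sum(len(s) for s in genome.values()) == 200_000
        assert sum(sizes.values()) == 200_000

    def test_deterministic(self):
        cfg = SimulationConfig(seed=42, n_scaffolds=1, scaffold_length=10_000)
        g1, _ = generate_genome(cfg)
        g2, _ = generate_genome(cfg)
        assert g1 == g2

    def test_gc_fraction(self):
        cfg = SimulationConfig(seed=3, n_scaffolds=1, scaffold_length=100_000,
                               gc_fraction=0.5)
        genome, _ = generate_genome(cfg)
        seq = genome["scaffold_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02  # ~13 binomial SD at n = 1e5


class TestGenerateGenes:
    def test_counts_and_disjoint_spans(self, small_config):
        _, sizes = generate_genome(small_config)
        genes, expr, cats, truth = generate_genes(small_config, sizes)
        assert len(genes) == small_config.n_genes
        assert len(truth.de_gene_ids) == small_config.n_de_genes
        by_scaf = {}
        for g in genes:
            by_scaf.setdefault(g.scaffold, []).append((g.start, g.end))
        for spans in by_scaf.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_cluster_profile_argmax_in_window(self, small_config):
        _, sizes = generate_genome(small_config)
        genes, expr, _, _ = generate_genes(small_config, sizes)
        windows = {1: (0, 10), 4: (18, 24), 3: (24, 40), 2: (40, 72)}
        tcols = [c for c in expr.columns if c.startswith("t")]
        times = np.array([float(c[1:]) for c in tcols])
        for gid, row in expr.iterrows():
            lo, hi = windows[int(row["assigned_cluster"])]
            argmax_t = times[np.argmax(row[tcols].to_numpy(dtype=float))]
            # the bump center is in the window; the sampled argmax is the
            # nearest timepoint to it
            nearest_in = min(times, key=lambda t: abs(t - (lo + hi) / 2))
            assert abs(argmax_t - np.clip(argmax_t, lo - 6, hi + 6)) == 0

    def test_too_small_genome_raises(self):
        cfg = SimulationConfig(n_scaffolds=1, scaffold_length=20_000, n_genes=50,
                               n_de_genes=5)
        with pytest.raises(ValueError, match="too small"):
            generate_genes(cfg, {"scaffold_1": 20_000})


class TestPeakLandscape:
    def test_counts_and_disjointness(self, small_dataset):
        master = small_dataset.master_peaks
        assert len(master) == small_dataset.config.n_peaks
        assert master.is_disjoint()
        for ps in small_dataset.replicate_peaks.values():
            assert len(ps) == small_dataset.config.n_peaks

    def test_differential_peaks_near_de_genes_bruteforce(self, small_dataset):
        ds = small_dataset
        de_spans = [g.span for g in ds.genes if g.gene_id in ds.truth.de_gene_ids]
        for iv in ds.master_peaks:
            if iv.id in ds.truth.differential_peak_ids:
                gap = min(
                    (iv.gap_to(s) for s in de_spans
                     if s.scaffold == iv.scaffold and iv.gap_to(s) is not None),
                    default=None,
                )
                assert gap is not None and gap <= ds.config.de_window

    def test_zero_jitter_replicates_identical(self):
        cfg = SimulationConfig(seed=2, n_scaffolds=1, scaffold_length=400_000,
                               n_genes=40, n_de_genes=8, n_peaks=100,
                               replicate_jitter_bp=0)
        _, sizes = generate_genome(cfg)
        genes, expr, _, truth = generate_genes(cfg, sizes)
        master, reps = generate_peak_landscape(cfg, sizes, genes, truth, expr)
        for ps in reps.values():
            assert ps == master

    def test_ground_truth_closure(self, small_dataset):
        ds = small_dataset
        peak_ids = {iv.id for iv in ds.master_peaks}
        gene_ids = {g.gene_id for g in ds.genes}
        assert ds.truth.differential_peak_ids <= peak_ids
        assert ds.truth.motif_planted_peak_ids <= ds.truth.differential_peak_ids
        assert ds.truth.de_gene_ids <= gene_ids


class TestGenerateCounts:
    def _peaks(self, n):
        return PeakSet(
            [GenomicInterval("s1", i * 1000, i * 1000 + 600, f"p{i:05d}")
             for i in range(n)]
        )

    def test_deterministic(self, small_config):
        peaks = self._peaks(100)
        c1, _ = generate_counts(small_config, peaks, GroundTruth(), "atac")
        c2, _ = generate_counts(small_config, peaks, GroundTruth(), "atac")
        assert c1.equals(c2)

    def test_null_mean_ratio_near_one(self):
        cfg = SimulationConfig(seed=6, dispersion=0.05, mean_depth=200.0)
        peaks = self._peaks(3000)
        truth = GroundTruth()
        counts, _ = generate_counts(cfg, peaks, truth, "atac")
        s = truth.size_factors
        tgt = [c for c in counts.columns if "_target_" in c]
        ref = [c for c in counts.columns if "_reference_" in c]
        z = counts / np.array([s[c] for c in counts.columns])
        # the raw ratio of 3-replicate means has a Jensen bias ~CV^2/3;
        # the log-ratio is symmetric and unbiased under the null
        log_ratio = np.log(z[tgt].mean(axis=1) / z[ref].mean(axis=1))
        se = log_ratio.std() / np.sqrt(len(log_ratio))
        assert abs(log_ratio.mean()) < 3 * se

    def test_planted_ratio_law(self):
        cfg = SimulationConfig(seed=8, planted_log2fc=1.5, mean_depth=500.0,
                               dispersion=0.02)
        peaks = self._peaks(2000)
        truth = GroundTruth(
            differential_peak_ids={f"p{i:05d}" for i in range(2000)},
            planted_log2fc_per_peak={f"p{i:05d}": 1.5 for i in range(2000)},
        )
        counts, _ = generate_counts(cfg, peaks, truth, "dnase")
        s = truth.size_factors
        z = counts / np.array([s[c] for c in counts.columns])
        tgt = [c for c in counts.columns if "_target_" in c]
        ref = [c for c in counts.columns if "_reference_" in c]
        log_ratio = np.log2(z[tgt].mean(axis=1) / z[ref].mean(axis=1))
        assert log_ratio.mean() == pytest.approx(1.5, abs=0.05)

    def test_poisson_limit_variance(self):
        cfg = SimulationConfig(seed=9, dispersion=0.0, baseline_sigma=0.0,
                               mean_depth=100.0)
        peaks = self._peaks(5000)
        truth = GroundTruth()
        counts, _ = generate_counts(cfg, peaks, truth, "atac")
        col = counts["atac_target_r1"]
        assert col.var() / col.mean() == pytest.approx(1.0, rel=0.1)


class TestEmitReads:
    def test_frip_near_target(self, small_dataset):
        ds = small_dataset
        col = ds.counts["atac"]["atac_target_r1"]
        # scale down for speed; FRiP is a ratio
        scaled = np.maximum((col.to_numpy() * 0.2).astype(int), 0)
        reads = emit_reads(ds.config, ds.master_peaks, scaled, ds.sizes, seed=5)
        from peakdiff.counts_qc import frip

        value, ok = frip(reads, ds.master_peaks)
        assert ok
        assert value == pytest.approx(ds.config.target_frip, abs=0.05)


class TestPlantMotifs:
    def test_rate_one_every_differential_peak_has_site(self, small_config):
        ds_cfg = SimulationConfig(
            **{**small_config.__dict__, "motif_plant_rate": 1.0}
        )
        ds = simulate_all(ds_cfg)
        site = ds.pwms[0].consensus
        assert ds.truth.motif_planted_peak_ids == ds.truth.differential_peak_ids
        for iv in ds.master_peaks:
            if iv.id in ds.truth.differential_peak_ids:
                assert site in ds.genome[iv.scaffold][iv.start : iv.end]

    def test_rate_zero_genome_unchanged(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "motif_plant_rate": 0.0})
        genome, sizes = generate_genome(cfg)
        genes, expr, _, truth = generate_genes(cfg, sizes)
        master, _ = generate_peak_landscape(cfg, sizes, genes, truth, expr)
        mutated = plant_motifs(cfg, genome, master, default_pwm_set(), truth)
        assert mutated == genome
        assert not truth.motif_planted_peak_ids

    def test_plant_count_binomial_bound(self):
        cfg = SimulationConfig(seed=13, n_scaffolds=4, scaffold_length=1_000_000,
                               n_genes=200, n_de_genes=100, n_peaks=800,
                               frac_differential=0.25, motif_plant_rate=0.5)
        ds = simulate_all(cfg)
        n = len(ds.truth.differential_peak_ids)
        k = len(ds.truth.motif_planted_peak_ids)
        # 99% binomial interval around n/2
        half = 2.58 * np.sqrt(n * 0.25)
        assert abs(k - n / 2) < half


class TestSimulateAllDeterminism:
    def test_identical_config_identical_outputs(self, small_config):
        d1 = simulate_all(small_config)
        d2 = simulate_all(small_config)
        assert d1.genome == d2.genome
        assert d1.master_peaks == d2.master_peaks
        for assay in d1.counts:
            assert d1.counts[assay].equals(d2.counts[assay])
        assert d1.manifest() == d2.manifest()
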