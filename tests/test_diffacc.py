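"""Differential accessibility: size factors, dispersion estimation and
the NB Wald test, checked against hand computations, a brute-force
likelihood-grid oracle and pyDESeq2 as an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from peakdiff.diffacc import (
    DifferentialCallSettings,
    estimate_dispersions,
    nb_wald_test,
    select_differential,
    size_factors,
)
from peakdiff.intervals import GenomicInterval, PeakSet
from peakdiff.simulate import GroundTruth, SimulationConfig, generate_counts


def _toy_matrix(rng, n_peaks=200, mean=100.0):
    mu = rng.lognormal(np.log(mean), 0.8, size=n_peaks)
    return pd.DataFrame(
        {f"r{k}": rng.poisson(mu) for k in range(4)},
        index=[f"p{i}" for i in range(n_peaks)],
    )


def _labels(counts, n_target=None):
    n = counts.shape[1] if n_target is None else 2 * n_target
    half = n // 2
    return np.array(["reference"] * half + ["target"] * (counts.shape[1] - half))


def _null_counts(seed, n_peaks, dispersion=0.05):
    cfg = SimulationConfig(seed=seed, dispersion=dispersion, frac_differential=1e-9)
    peaks = PeakSet(
        [GenomicInterval("s1", i * 1000, i * 1000 + 600, f"p{i:05d}")
         for i in range(n_peaks)]
    )
    counts, _ = generate_counts(cfg, peaks, GroundTruth(), "atac")
    return counts


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5, 80], "b": [10, 20, 5, 80]})
        assert size_factors(counts) == pytest.approx([1.0, 1.0])

    def test_doubled_column_hand_oracle(self):
        # 4-peak matrix, 4 samples, last column doubled.  With geometric
        # means over all samples the doubled column's factor is 2^(3/4)
        # and the others 2^(-1/4); only the ratio (= 2) is identified.
        base = np.array([10.0, 20.0, 40.0, 80.0])
        counts = pd.DataFrame(
            {"a": base, "b": base, "c": base, "d": 2 * base}
        )
        f = size_factors(counts)
        assert f[:3] == pytest.approx([2 ** -0.25] * 3)
        assert f[3] == pytest.approx(2 ** 0.75)
        assert f[3] / f[0] == pytest.approx(2.0)

    def test_invariant_to_peak_order(self, rng):
        counts = _toy_matrix(rng)
        perm = rng.permutation(len(counts))
        assert size_factors(counts) == pytest.approx(
            size_factors(counts.iloc[perm])
        )

    def test_all_peaks_with_zero_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestEstimateDispersions:
    def test_poisson_data_near_zero(self, rng):
        counts = _toy_matrix(rng, n_peaks=500)
        disp = estimate_dispersions(counts, np.ones(4), _labels(counts))
        assert np.median(disp) < 0.01

    def test_recovers_planted_dispersion(self):
        # alpha = 0.2, 6 replicates per condition
        rng = np.random.default_rng(8)
        mu = rng.lognormal(np.log(200), 0.5, size=800)
        alpha = 0.2
        counts = pd.DataFrame(
            {f"r{k}": rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
             for k in range(12)}
        )
        labels = np.array(["reference"] * 6 + ["target"] * 6)
        disp = estimate_dispersions(counts, np.ones(12), labels)
        assert 0.1 < np.median(disp) < 0.4

    def test_constant_counts_floor(self):
        counts = pd.DataFrame({c: [50, 20, 10] for c in "abcd"})
        disp = estimate_dispersions(
            counts, np.ones(4), np.array(["reference", "reference", "target", "target"])
        )
        assert np.allclose(disp, 1e-8)

    def test_single_replicate_fallback_warns(self):
        counts = pd.DataFrame({"a": [10, 50, 5], "b": [12, 40, 9]})
        with pytest.warns(UserWarning, match="single replicate"):
            estimate_dispersions(
                counts, np.ones(2), np.array(["reference", "target"])
            )


def nb_loglik(y, x, s, alpha, b0, b1):
    """Independent NB log-likelihood for the grid-search oracle."""
    mu = s * np.exp(b0 + b1 * x)
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


class TestNbWaldTest:
    def test_single_peak_matches_grid_oracle(self):
        # worked example: (10, 12, 9) vs (40, 44, 38), alpha fixed 0.01
        y = np.array([10, 12, 9, 40, 44, 38], dtype=float)
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        counts = pd.DataFrame([y], index=["p0"], columns=[f"s{k}" for k in range(6)])
        res = nb_wald_test(
            counts, np.where(x == 1, "target", "reference"),
            np.ones(6), np.array([0.01]),
        )
        b0_grid = np.linspace(np.log(5), np.log(20), 301)
        b1_grid = np.linspace(0.5, 2.5, 401)
        ll = np.array(
            [[nb_loglik(y, x, 1.0, 0.01, b0, b1) for b1 in b1_grid] for b0 in b0_grid]
        )
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        oracle_lfc = b1_grid[j] / np.log(2)
        assert res["log2FoldChange"].iloc[0] == pytest.approx(oracle_lfc, abs=0.1)
        assert res["log2FoldChange"].iloc[0] == pytest.approx(np.log2(4), abs=0.15)
        assert res["stat"].iloc[0] == pytest.approx(
            res["log2FoldChange"].iloc[0] / res["lfcSE"].iloc[0]
        )

    def test_label_swap_negates_lfc_keeps_p(self):
        counts = _null_counts(3, 300)
        labels = np.array(
            ["target" if "_target_" in c else "reference" for c in counts.columns]
        )
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, labels)
        res = nb_wald_test(counts, labels, sf, disp)
        swapped = np.where(labels == "target", "reference", "target")
        res2 = nb_wald_test(counts, swapped, sf, disp)
        assert np.allclose(res2["log2FoldChange"], -res["log2FoldChange"], atol=1e-6)
        assert np.allclose(res2["stat"], -res["stat"], atol=1e-6)
        assert np.allclose(res2["pvalue"], res["pvalue"], atol=1e-9)

    def test_all_zero_peak_missing_stats(self):
        counts = pd.DataFrame(
            {"a": [0, 10], "b": [0, 12], "c": [0, 30], "d": [0, 33]},
            index=["z", "p"],
        )
        labels = np.array(["reference", "reference", "target", "target"])
        res = nb_wald_test(counts, labels, np.ones(4), np.array([0.05, 0.05]))
        assert res.loc["z", "baseMean"] == 0
        assert np.isnan(res.loc["z", "pvalue"])
        assert np.isfinite(res.loc["p", "pvalue"])

    def test_null_type_one_error_calibrated(self):
        counts = _null_counts(1, 10_000)
        labels = np.array(
            ["target" if "_target_" in c else "reference" for c in counts.columns]
        )
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, labels)
        p = nb_wald_test(counts, labels, sf, disp)["pvalue"].to_numpy()
        for a in (0.05, 0.1, 0.2):
            se = np.sqrt(a * (1 - a) / len(p))
            assert abs((p < a).mean() - a) < 3 * se

    def test_planted_lfc_recovered(self):
        cfg = SimulationConfig(seed=5, planted_log2fc=2.0)
        peaks = PeakSet(
            [GenomicInterval("s1", i * 1000, i * 1000 + 600, f"p{i:04d}")
             for i in range(500)]
        )
        truth = GroundTruth(
            differential_peak_ids={f"p{i:04d}" for i in range(500)},
            planted_log2fc_per_peak={f"p{i:04d}": 2.0 for i in range(500)},
        )
        counts, _ = generate_counts(cfg, peaks, truth, "atac")
        labels = np.array(
            ["target" if "_target_" in c else "reference" for c in counts.columns]
        )
        # every peak is differential here, so median-of-ratios would
        # absorb the effect: use the generator's true depth factors
        sf = np.array([truth.size_factors[c] for c in counts.columns])
        disp = estimate_dispersions(counts, sf, labels)
        res = nb_wald_test(counts, labels, sf, disp)
        assert res["log2FoldChange"].mean() == pytest.approx(2.0, abs=0.25)

    def test_agrees_with_pydeseq2(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimulationConfig(seed=7, frac_differential=0.1)
        peaks = PeakSet(
            [GenomicInterval("s1", i * 1000, i * 1000 + 600, f"p{i:04d}")
             for i in range(300)]
        )
        truth = GroundTruth(
            differential_peak_ids={f"p{i:04d}" for i in range(30)},
            planted_log2fc_per_peak={f"p{i:04d}": 2.0 for i in range(30)},
        )
        counts, _ = generate_counts(cfg, peaks, truth, "atac")
        meta = pd.DataFrame(
            {"condition": ["target" if "_target_" in c else "reference"
                           for c in counts.columns]},
            index=counts.columns,
        )
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(
            dds, contrast=["condition", "target", "reference"], quiet=True
        )
        ds.summary()
        ref = ds.results_df

        labels = np.array(meta["condition"])
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, labels)
        mine = nb_wald_test(counts, labels, sf, disp)
        r = np.corrcoef(mine["log2FoldChange"], ref["log2FoldChange"])[0, 1]
        assert r > 0.999
        assert (mine["log2FoldChange"] - ref["log2FoldChange"]).abs().max() < 0.1


class TestSelectDifferential:
    def _results(self, p, lfc):
        return pd.DataFrame(
            {"baseMean": 10.0, "log2FoldChange": lfc, "lfcSE": 1.0,
             "stat": lfc, "pvalue": p},
            index=[f"p{i}" for i in range(len(p))],
        )

    def test_no_peaks_pass_large_p(self):
        res = self._results([0.5] * 4, [1.0] * 4)
        assert select_differential(res, DifferentialCallSettings(alpha=0.2)) == []

    def test_near_threshold_peak_included(self):
        # nominal p 0.19 with positive fold change passes alpha 0.2
        res = self._results([0.19, 0.21], [1.0, 1.0])
        sel = select_differential(res, DifferentialCallSettings(alpha=0.2))
        assert sel == ["p0"]

    def test_direction_filter(self):
        res = self._results([0.01, 0.01], [2.0, -2.0])
        up = select_differential(
            res, DifferentialCallSettings(0.1, "enriched-in-target")
        )
        down = select_differential(
            res, DifferentialCallSettings(0.1, "enriched-in-reference")
        )
        both = select_differential(res, DifferentialCallSettings(0.1, "both"))
        assert (up, down) == (["p0"], ["p1"])
        assert both == ["p0", "p1"]

    def test_null_selection_rate(self):
        counts = _null_counts(2, 10_000)
        labels = np.array(
            ["target" if "_target_" in c else "reference" for c in counts.columns]
        )
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, labels)
        res = nb_wald_test(counts, labels, sf, disp)
        sel = select_differential(res, DifferentialCallSettings(0.1, "both"))
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(len(sel) / 10_000 - 0.1) < 3 * se
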