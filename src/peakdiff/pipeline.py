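"""End-to-end orchestration of the differential-accessibility analysis.

Stages, in order: ``simulate`` (synthetic data with ground truth) →
``rps`` (reference peak set per assay) → ``qc`` (FRiP + replicate
concordance) → ``diffacc`` (NB-Wald differential peaks per assay) →
``crossassay`` (overlapping differential peaks) → ``annotate``
(peak-to-gene categories) → ``enrich`` (Fisher enrichment tables) →
``motifs`` (two-step shuffled-control motif calls) → ``report``.

Every stage writes plain-text outputs into the run directory and the
next stage reads them back through the package's own readers, so each
intermediate is inspectable and each stage is testable in isolation.
A run manifest (config hash + per-file checksums) records provenance;
deterministic stages reproduce identical checksums on re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotation import annotate_peaks, location_distribution
from .counts_qc import SampleMeta, equalize_depth_matrix, frip, replicate_concordance
from .diffacc import (
    DifferentialCallSettings,
    estimate_dispersions,
    nb_wald_test,
    select_differential,
    size_factors,
)
from .enrichment import (
    assign_expression_class,
    assign_temporal_cluster,
    category_enrichment,
    class_enrichment,
    enrichment_table,
    proximity_enrichment,
    ExpressionProfile,
)
from .intervals import (
    GenomicInterval,
    OverlapCriterion,
    PeakSet,
    build_reference_peak_set,
    cross_assay_merge,
    genome_coverage,
)
from .motifs import ame_two_step, read_meme, write_meme
from .simulate import (
    ASSAYS,
    SimulationConfig,
    emit_reads,
    peak_sequences,
    simulate_all,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name, prior outputs are kept."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_frac: float = 0.75
    alpha_atac: float = 0.2
    alpha_dnase: float = 0.1
    window_bp: int = 10_000
    motif_alpha: float = 0.05
    motif_p_threshold: float = 1e-5
    n_nondiff_motif_seqs: int = 300  # non-differential background sample
    frip_read_target: int = 40_000  # reads emitted per sample for the FRiP gate
    outdir: str | Path = "peakdiff_run"

    def __post_init__(self) -> None:
        for a in (self.alpha_atac, self.alpha_dnase, self.motif_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha values must be in (0, 1)")


@dataclass
class RunManifest:
    config_hash: str
    started: float
    checksums: dict[str, str] = field(default_factory=dict)

    def record(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[str(path.relative_to(root))] = digest


def _alpha_for(config: PipelineConfig, assay: str) -> float:
    return config.alpha_atac if assay == "atac" else config.alpha_dnase


def map_counts_to_rps(
    counts: pd.DataFrame, master: PeakSet, rps: PeakSet
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Reindex a master-peak count matrix onto the RPS.

    Each master peak maps to the RPS peak covering it with the greatest
    overlap; master peaks merged into one RPS interval have their
    counts summed.  Returns the RPS-indexed counts and the
    master-id -> rps-id map.
    """
    rps_arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for scaf in rps.scaffolds():
        ivs = rps.by_scaffold(scaf)
        rps_arrays[scaf] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            [iv.id or f"{scaf}:{iv.start}" for iv in ivs],
        )
    mapping: dict[str, str] = {}
    for iv in master:
        if iv.scaffold not in rps_arrays:
            continue
        starts, ends, ids = rps_arrays[iv.scaffold]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            continue
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        best = int(np.argmax(ov))
        if ov[best] > 0 and iv.id is not None:
            mapping[iv.id] = ids[lo + best]
    grouped = counts.loc[[m for m in counts.index if m in mapping]].copy()
    grouped["__rps"] = [mapping[m] for m in grouped.index]
    out = grouped.groupby("__rps").sum()
    out.index.name = "peak_id"
    return out, mapping


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to
    ``report.json`` in the run directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        started=time.time(),
    )
    report: dict = {"stages": []}
    stage = "simulate"
    try:
        ds = simulate_all(config.simulation)
        io.write_fasta(ds.genome, outdir / "genome.fa")
        io.write_chrom_sizes(ds.sizes, outdir / "genome.sizes")
        io.write_gff3(ds.genes, outdir / "genes.gff3")
        io.write_bed(ds.master_peaks, outdir / "master_peaks.bed")
        peaks_dir = outdir / "peaks"
        peaks_dir.mkdir(exist_ok=True)
        for (assay, cond, rep), ps in ds.replicate_peaks.items():
            io.write_bed(ps, peaks_dir / f"{assay}_{cond}_r{rep}.bed")
        for assay in ASSAYS:
            io.write_count_matrix(ds.counts[assay], outdir / f"counts_{assay}.tsv")
            pd.DataFrame(
                [asdict(s) for s in ds.samples[assay]]
            ).to_csv(outdir / f"samples_{assay}.tsv", sep="\t", index=False)
        ds.expression.to_csv(outdir / "expression.tsv", sep="\t")
        with open(outdir / "categories.tsv", "w") as fh:
            fh.write("gene_id\tcategory\n")
            for gid, cats in sorted(ds.categories.items()):
                for c in cats:
                    fh.write(f"{gid}\t{c}\n")
        pd.DataFrame(
            {"gene_id": sorted(ds.truth.de_gene_ids)}
        ).to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
        write_meme(ds.pwms, outdir / "motifs.meme")
        io.write_json(ds.manifest(), outdir / "ground_truth.json")
        report["stages"].append(stage)

        # --- rps ---------------------------------------------------------
        stage = "rps"
        criterion = OverlapCriterion(min_fraction=config.min_frac)
        genome_size = sum(ds.sizes.values())
        rps: dict[str, PeakSet] = {}
        for assay in ASSAYS:
            reps = [
                io.read_bed(p)
                for p in sorted(peaks_dir.glob(f"{assay}_*_r*.bed"))
            ]
            merged = build_reference_peak_set(reps, criterion)
            # stable ids for downstream joins
            named = PeakSet(
                [
                    GenomicInterval(iv.scaffold, iv.start, iv.end,
                                    f"{assay}_rps_{k + 1:05d}")
                    for k, iv in enumerate(merged)
                ],
                label=f"{assay}_rps",
            )
            rps[assay] = named
            io.write_bed(named, outdir / f"rps_{assay}.bed")
            report[f"rps_{assay}_n_peaks"] = len(named)
            report[f"rps_{assay}_mean_width"] = (
                named.total_bp / len(named) if len(named) else 0.0
            )
            report[f"rps_{assay}_genome_coverage"] = genome_coverage(
                named, genome_size
            )
        report["stages"].append(stage)

        # --- qc ----------------------------------------------------------
        stage = "qc"
        qc_out: dict = {}
        retained: dict[str, list[str]] = {}
        for assay in ASSAYS:
            counts = io.read_count_matrix(outdir / f"counts_{assay}.tsv")
            sheet = pd.read_csv(outdir / f"samples_{assay}.tsv", sep="\t")
            metas = [
                SampleMeta(r.sample_id, r.assay, r.condition, r.replicate, r.depth)
                for r in sheet.itertuples()
            ]
            qc = replicate_concordance(counts, metas)
            # FRiP on depth-scaled read realizations (FRiP is a ratio;
            # the gate does not need full depth)
            frips = {}
            for cond in ("target", "reference"):
                col = f"{assay}_{cond}_r1"
                scale = config.frip_read_target / max(counts[col].sum(), 1)
                scaled = np.maximum(
                    np.round(counts[col].to_numpy() * scale), 0
                ).astype(int)
                reads = emit_reads(
                    config.simulation, ds.master_peaks, scaled, ds.sizes,
                    seed=config.simulation.seed + 17,
                )
                value, ok = frip(reads, rps[assay])
                frips[col] = {"frip": value, "pass": bool(ok)}
            retained[assay] = sorted(qc.retained_samples)
            qc_out[assay] = {
                "frip": frips,
                "pearson": qc.pearson_matrix.round(4).to_dict(),
                "retained": sorted(qc.retained_samples),
                "excluded": sorted(qc.excluded_samples),
            }
        io.write_json(qc_out, outdir / "qc.json")
        report["qc"] = {
            a: {"retained": qc_out[a]["retained"], "excluded": qc_out[a]["excluded"]}
            for a in ASSAYS
        }
        report["frip"] = {
            a: {k: v["frip"] for k, v in qc_out[a]["frip"].items()} for a in ASSAYS
        }
        report["stages"].append(stage)

        # --- diffacc -----------------------------------------------------
        stage = "diffacc"
        diff_sets: dict[str, PeakSet] = {}
        results_by_assay: dict[str, pd.DataFrame] = {}
        rps_truth_diff: dict[str, set[str]] = {}
        for assay in ASSAYS:
            counts = io.read_count_matrix(outdir / f"counts_{assay}.tsv")
            keep = [c for c in counts.columns if c in set(retained[assay])]
            counts = counts[keep]
            rps_counts, mapping = map_counts_to_rps(
                counts, ds.master_peaks, rps[assay]
            )
            rps_truth_diff[assay] = {
                mapping[m]
                for m in ds.truth.differential_peak_ids
                if m in mapping
            }
            eq = equalize_depth_matrix(rps_counts, seed=config.simulation.seed + 23)
            labels = np.array(
                ["target" if "_target_" in c else "reference" for c in eq.columns]
            )
            sf = size_factors(eq)
            disp = estimate_dispersions(eq, sf, labels)
            res = nb_wald_test(eq, labels, sf, disp)
            results_by_assay[assay] = res
            coords = {iv.id: iv for iv in rps[assay]}
            tbl = res.reset_index()
            tbl.insert(1, "scaffold", [coords[p].scaffold for p in res.index])
            tbl.insert(2, "start", [coords[p].start for p in res.index])
            tbl.insert(3, "end", [coords[p].end for p in res.index])
            tbl.to_csv(outdir / f"differential_{assay}.tsv", sep="\t", index=False)
            settings = DifferentialCallSettings(
                alpha=_alpha_for(config, assay), direction="enriched-in-target"
            )
            diff = select_differential(res, settings, rps[assay])
            diff_sets[assay] = diff
            io.write_bed(diff, outdir / f"differential_{assay}.bed")
            truth_ids = rps_truth_diff[assay]
            called = set(iv.id for iv in diff)
            tp = len(called & truth_ids)
            report[f"differential_{assay}_n"] = len(diff)
            report[f"differential_{assay}_recall"] = (
                tp / len(truth_ids) if truth_ids else float("nan")
            )
            report[f"differential_{assay}_precision"] = (
                tp / len(called) if called else float("nan")
            )
        report["stages"].append(stage)

        # --- crossassay --------------------------------------------------
        stage = "crossassay"
        overlap = cross_assay_merge(
            diff_sets["atac"], diff_sets["dnase"], criterion
        )
        overlap = PeakSet(
            [
                GenomicInterval(iv.scaffold, iv.start, iv.end, f"ovl_{k + 1:04d}")
                for k, iv in enumerate(overlap)
            ],
            label="overlapping_differential",
        )
        io.write_bed(overlap, outdir / "overlapping_differential.bed")
        report["overlapping_differential_n"] = len(overlap)
        report["stages"].append(stage)

        # --- annotate ----------------------------------------------------
        stage = "annotate"
        genes = io.read_gff3(outdir / "genes.gff3")
        ann_rows = []
        for assay in ASSAYS:
            anns = annotate_peaks(diff_sets[assay], genes, window_bp=config.window_bp)
            for a in anns:
                ann_rows.append(
                    {"assay": assay, "peak_id": a.peak_id, "category": a.category,
                     "subcategory": a.subcategory, "nearest_gene": a.nearest_gene,
                     "distance_bp": a.distance_bp,
                     "genes_within_10kb": ",".join(sorted(a.genes_within_10kb))}
                )
        pd.DataFrame(ann_rows).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        dist = location_distribution(rps["atac"], genes, window_bp=config.window_bp)
        dist.to_csv(outdir / "location_distribution_atac_rps.tsv", sep="\t",
                    index=False)
        report["location_distribution_atac_rps"] = dict(
            zip(dist["category"], dist["fraction"])
        )
        report["stages"].append(stage)

        # --- enrich ------------------------------------------------------
        stage = "enrich"
        de_path = outdir / "de_genes.tsv"
        if not de_path.exists():
            raise FileNotFoundError("DE gene list missing (de_genes.tsv)")
        de_ids = set(pd.read_csv(de_path, sep="\t")["gene_id"])
        enr_results = []
        for assay in ASSAYS:
            r = proximity_enrichment(
                diff_sets[assay], rps[assay], genes, de_ids, config.window_bp
            )
            r.property_name = f"{assay}_diff_within_10kb_of_DE_gene"
            enr_results.append(r)
            report[f"proximity_fold_{assay}"] = r.fold_enrichment
            report[f"proximity_p_{assay}"] = r.p_value
            report[f"diff_{assay}_near_de"] = r.table.a

        from .annotation import genes_within_window

        def gene_set_near(peakset: PeakSet) -> set[str]:
            out: set[str] = set()
            for iv in peakset:
                out |= genes_within_window(iv, genes, config.window_bp)
            return out

        cat_df = pd.read_csv(outdir / "categories.tsv", sep="\t")
        cat_map: dict[str, list[str]] = {}
        for r_ in cat_df.itertuples():
            cat_map.setdefault(r_.gene_id, []).append(r_.category)
        near_diff = gene_set_near(diff_sets["atac"]) | gene_set_near(
            diff_sets["dnase"]
        )
        nondiff_atac = PeakSet(
            [iv for iv in rps["atac"]
             if iv.id not in {p.id for p in diff_sets["atac"]}]
        )
        near_nondiff = gene_set_near(nondiff_atac) - near_diff
        cat_results = category_enrichment(near_diff, near_nondiff, cat_map)
        enr_results.extend(cat_results)
        bio = next(
            (r for r in cat_results if r.property_name == "biomineralization"), None
        )
        if bio is not None:
            report["biomineralization_fold"] = bio.fold_enrichment
            report["biomineralization_adj_p"] = bio.adjusted_p

        expr = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
        tcols = [c for c in expr.columns if c.startswith("t")]
        profiles = {
            gid: ExpressionProfile(
                gid, float(row["fpkm_24hpf"]),
                {float(c[1:]): float(row[c]) for c in tcols},
            )
            for gid, row in expr.iterrows()
        }
        de_class = {g: assign_expression_class(profiles[g].fpkm_24hpf)
                    for g in de_ids if g in profiles}
        de_cluster = {
            g: str(assign_temporal_cluster(profiles[g]))
            for g in de_ids
            if g in profiles and assign_temporal_cluster(profiles[g]) is not None
        }
        near_overlap = gene_set_near(overlap) & de_ids
        if near_overlap:
            for r in class_enrichment(near_overlap, de_class):
                r.property_name = f"expression_class_{r.property_name}"
                enr_results.append(r)
            for r in class_enrichment(near_overlap, de_cluster):
                r.property_name = f"temporal_cluster_{r.property_name}"
                enr_results.append(r)
        enrichment_table(enr_results).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        report["stages"].append(stage)

        # --- motifs ------------------------------------------------------
        stage = "motifs"
        genome = io.read_fasta(outdir / "genome.fa")
        pwms = read_meme(outdir / "motifs.meme")
        # sequences come from the RPS intervals; differential vs a
        # sample of non-differential peaks
        all_seqs = peak_sequences(genome, rps["atac"])
        diff_rps_ids = {
            i for a in ASSAYS for i in (iv.id for iv in diff_sets[a])
        }
        diff_seqs = [
            s for i, s in all_seqs.items()
            if i in {iv.id for iv in diff_sets["atac"]}
        ]
        nondiff_ids = sorted(set(all_seqs) - diff_rps_ids)
        rng = np.random.default_rng(config.simulation.seed + 31)
        pick = rng.choice(
            len(nondiff_ids),
            size=min(config.n_nondiff_motif_seqs, len(nondiff_ids)),
            replace=False,
        )
        nondiff_seqs = [all_seqs[nondiff_ids[k]] for k in sorted(pick)]
        calls = ame_two_step(
            diff_seqs, nondiff_seqs, pwms,
            alpha=config.motif_alpha, seed=config.simulation.seed + 37,
            p_threshold=config.motif_p_threshold,
        )
        pd.DataFrame([asdict(c) for c in calls]).to_csv(
            outdir / "motif_calls.tsv", sep="\t", index=False
        )
        report["motifs_enriched"] = [
            c.motif_id for c in calls if c.enriched_in_differential
        ]
        report["stages"].append(stage)

        # --- report ------------------------------------------------------
        stage = "report"
        for path in sorted(outdir.rglob("*")):
            if path.is_file() and path.name not in ("report.json", "manifest.json"):
                manifest.record(path, outdir)
        io.write_json(asdict(manifest), outdir / "manifest.json")
        io.write_json(report, outdir / "report.json")
        report["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return report
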