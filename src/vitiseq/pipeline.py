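"""End-to-end orchestration: simulate -> quantify -> calls -> cluster ->
enrich -> platform comparison, with every printed constant of the analysis
collected in one audited configuration object."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as clustermod
from . import diffexpr, enrich, io, platform, quantify, simulate
from .errors import ConfigurationError
from .schema import STAGES, catalog_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable knobs of a pipeline run, with the study defaults."""

    outdir: str = "vitiseq_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    # synthetic data
    n_transcripts: int = 10_000
    n_go_terms: int = 200
    reads_per_stage: int = 50_000
    multimap_rate: float = 0.15
    qc_fail_rate: float = 0.02
    crosshyb_fraction: float = 0.1
    platform_rho: float = 0.7

    # quantification
    min_read_length: int = 60
    max_ambiguous: int = 2
    min_identity: float = 0.98
    min_aligned_fraction: float = 0.5
    detection_floor: float = 0.5
    min_unique: int = 5

    # differential expression
    fold_floor: float = 0.1
    min_fold: float = 3.0

    # clustering
    k: int = 20
    n_runs: int = 1000
    required_repeats: int = 3

    # enrichment
    fdr_cutoff: float = 0.05

    # platform comparison
    intensity_percentile: float = 25.0
    rpkm_comparison_floor: float = 0.5

    def validate(self) -> None:
        if len(self.stages) != 4:
            raise ConfigurationError("exactly 4 stages are required")
        positive = {
            "n_transcripts": self.n_transcripts,
            "reads_per_stage": self.reads_per_stage,
            "min_read_length": self.min_read_length,
            "detection_floor": self.detection_floor,
            "min_unique": self.min_unique,
            "fold_floor": self.fold_floor,
            "min_fold": self.min_fold,
            "k": self.k,
            "n_runs": self.n_runs,
            "fdr_cutoff": self.fdr_cutoff,
            "rpkm_comparison_floor": self.rpkm_comparison_floor,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-study pipeline; returns the run manifest.

    Writes every stage artifact under ``config.outdir`` as tab-separated
    tables (plus the catalog FASTA), a machine-readable ``summary.json``
    and a ``manifest.json`` listing all outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output directory {outdir}: {exc}")

    t0 = time.perf_counter()
    paths: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        paths[name] = str(io.write_table(frame, outdir / f"{name}.tsv"))

    logger.info("simulating catalog of %d transcripts", config.n_transcripts)
    catalog, truth = simulate.generate_catalog(
        config.n_transcripts,
        config.n_go_terms,
        seed=config.seed,
        platform_rho=config.platform_rho,
    )
    annotation_frame = catalog_to_frame(catalog)
    save("catalog_annotation", annotation_frame)
    paths["catalog_fasta"] = str(
        io.write_catalog_fasta(catalog, outdir / "catalog.fasta", seed=config.seed)
    )

    logger.info("simulating %d reads per stage", config.reads_per_stage)
    reads, candidates = simulate.generate_alignments(
        truth,
        catalog,
        reads_per_stage=config.reads_per_stage,
        multimap_rate=config.multimap_rate,
        qc_fail_rate=config.qc_fail_rate,
        seed=config.seed + 1,
    )
    save("reads", reads)
    save("alignment_candidates", candidates)

    logger.info("quantifying")
    lengths = pd.Series(
        {r.transcript_id: r.length for r in catalog}, name="length"
    )
    matrix = quantify.build_expression_matrix(
        reads,
        candidates,
        lengths,
        stages=config.stages,
        min_length=config.min_read_length,
        max_ambiguous=config.max_ambiguous,
        min_identity=config.min_identity,
        min_aligned_fraction=config.min_aligned_fraction,
    )
    save("expression_matrix", matrix.to_frame())
    bins = quantify.abundance_bins(
        matrix, floor=config.detection_floor, min_unique=config.min_unique
    )
    save("abundance_bins", bins.reset_index())

    logger.info("calling stage-specific up-regulation")
    calls = diffexpr.stage_specific_calls(
        matrix.rpkm, min_fold=config.min_fold, floor=config.fold_floor
    )
    veraison = diffexpr.veraison_calls(
        matrix.rpkm, min_fold=config.min_fold, floor=config.fold_floor
    )
    save("stage_specific_calls", calls)
    save("veraison_calls", veraison)
    summary_calls = diffexpr.call_summary(calls, veraison)
    save("call_summary", summary_calls.reset_index())

    logger.info("clustering (k=%d, %d restarts)", config.k, config.n_runs)
    profiles, report = clustermod.normalize_and_filter(
        matrix.rpkm, all_low_floor=config.detection_floor
    )
    save("normalization_report", report)
    result = clustermod.kmeans_stable(
        profiles,
        k=config.k,
        n_runs=config.n_runs,
        required_repeats=config.required_repeats,
        seed=config.seed + 2,
    )
    result = clustermod.label_archetypes(result)
    assignments = result.assignments.to_frame().reset_index(names="transcript_id")
    assignments["archetype_label"] = [
        result.archetype_labels.get(c, "unlabeled") for c in assignments["cluster"]
    ]
    save("clusters", assignments)

    logger.info("GO enrichment per cluster")
    go_map = {r.transcript_id: r.go_terms for r in catalog}
    term_results, group_scores = enrich.enrich_all_clusters(
        result.assignments,
        lengths.index,
        go_map,
        truth.term_groups,
        fdr_cutoff=config.fdr_cutoff,
    )
    save("enrichment_terms", term_results)
    save("group_scores", group_scores)

    logger.info("platform comparison")
    probesets = simulate.generate_probeset_data(
        truth,
        catalog,
        crosshyb_fraction=config.crosshyb_fraction,
        seed=config.seed + 3,
    )
    save("probesets", probesets)
    pairs = platform.build_matched_pairs(probesets, matrix.rpkm)
    pairs = platform.apply_expression_floors(
        pairs,
        intensity_percentile=config.intensity_percentile,
        rpkm_floor=config.rpkm_comparison_floor,
    )
    save("matched_pairs", pairs)
    stage_rho = platform.global_stage_correlation(pairs)
    pattern_rho, histogram = platform.pattern_correlation_histogram(pairs)
    save("pattern_histogram", histogram.rename_axis("bin").reset_index())

    detected = matrix.detected(config.detection_floor, config.min_unique)
    cluster_sizes = result.assignments.value_counts().sort_index()
    summary = {
        "seed": config.seed,
        "n_transcripts": config.n_transcripts,
        "total_reads": int(len(reads)),
        "reads_counted": {s: float(matrix.total_mapped[s]) for s in config.stages},
        "detected_per_stage": {s: int(detected[s].sum()) for s in config.stages},
        "detected_any_stage": int(detected.any(axis=1).sum()),
        "abundance_bins": {s: bins[s].to_dict() for s in config.stages},
        "stage_specific_counts": {
            c: int((calls["call"] == c).sum())
            for c in ("young", "early_veraison", "late_veraison", "ripe", "none")
        },
        "veraison_pair_count": int(veraison["flagged"].sum()),
        "profiles_clustered": int(len(profiles)),
        "k": config.k,
        "best_objective": result.best_objective,
        "times_found": result.times_found,
        "cluster_sizes": {int(k): int(v) for k, v in cluster_sizes.items()},
        "top_group_scores": group_scores.head(10).to_dict(orient="records"),
        "platform_stage_rho": stage_rho,
        "pattern_rho_ge_0.9_fraction": float((pattern_rho >= 0.9).mean())
        if len(pattern_rho)
        else None,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    paths["summary"] = str(outdir / "summary.json")

    manifest = {"outputs": paths, "summary": summary}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("run complete in %.1fs", summary["runtime_s"])
    return manifest
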