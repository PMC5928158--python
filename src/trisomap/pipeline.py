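"""End-to-end orchestration of differential transcriptome-map runs.

Stage order: read -> linearize -> resolve probes -> threshold -> intra-sample
normalize -> scaled quantile normalize (joint reference over both pools) ->
pool per-locus consensus -> differential map -> extreme-locus flags ->
segment windows -> hypergeometric test + FDR -> dedup -> single-gene mode ->
chromosome summary.  Every stage appends a record-count line to the run log
so no silent record loss can occur.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .annotation import GenomeAnnotation, Platform
from .integrate import PoolResult, _round2, differential_map, pool_loci
from .normalize import (
    DEFAULT_N_QUANTILE_POINTS,
    DEFAULT_THRESHOLD_FACTOR,
    NormalizedSample,
    build_quantile_reference,
    intra_sample_normalize,
    scaled_quantile_normalize,
    threshold_nonpositive,
)
from .qpcr import correlate_ratios, load_validation_panel
from .segments import (
    MapConfig,
    build_segments,
    chromosome_mean_ratio,
    deduplicate_segments,
    flag_extreme_loci,
    single_gene_mode,
    tag_and_test_segments,
)

log = logging.getLogger(__name__)


@dataclass
class MapRunResult:
    """Bundle of outputs from one differential map run."""

    pool_a: PoolResult
    pool_b: PoolResult
    comparison: pd.DataFrame
    segments: pd.DataFrame
    called_segments: pd.DataFrame
    single_gene: pd.DataFrame
    chromosome_summary: pd.DataFrame
    stage_log: list[dict] = field(default_factory=list)


def _log_stage(stage_log: list[dict], stage: str, **counts) -> None:
    entry = {"stage": stage, **counts}
    stage_log.append(entry)
    log.info("stage %s: %s", stage, counts)


def run_differential_map(
    samples_a: list[tio.Sample],
    samples_b: list[tio.Sample],
    platforms: dict[str, Platform],
    annotation: GenomeAnnotation,
    config: MapConfig | None = None,
    *,
    n_quantile_points: int = DEFAULT_N_QUANTILE_POINTS,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> MapRunResult:
    """Run the full differential pipeline on in-memory samples."""
    if config is None:
        config = MapConfig()
    if not samples_a:
        raise ValueError("pool A is empty")
    if not samples_b:
        raise ValueError("pool B is empty")
    stage_log: list[dict] = []

    def prepare(samples: list[tio.Sample], pool: str) -> list[NormalizedSample]:
        normalized = []
        for sample in samples:
            linear = tio.linearize(sample)
            platform = platforms[linear.platform_id]
            resolved = tio.resolve_probes(linear, platform, annotation)
            _log_stage(
                stage_log,
                "resolve",
                pool=pool,
                sample=sample.sample_id,
                emitted=resolved.n_emitted,
                unmapped=resolved.n_unmapped,
                missing=resolved.n_missing,
                feature_count=platform.feature_count,
            )
            records = resolved.records.copy()
            records["value"] = threshold_nonpositive(
                records["value"].to_numpy(), threshold_factor
            )
            normalized.append(
                intra_sample_normalize(
                    records, sample_id=sample.sample_id, condition=sample.condition
                )
            )
        return normalized

    intra_a = prepare(samples_a, "A")
    intra_b = prepare(samples_b, "B")
    # joint reference across both pools: pool-level shifts must survive
    ref = build_quantile_reference(intra_a + intra_b, n_quantile_points)
    norm_a = [scaled_quantile_normalize(s, ref) for s in intra_a]
    norm_b = [scaled_quantile_normalize(s, ref) for s in intra_b]
    _log_stage(stage_log, "normalize", n_samples=len(norm_a) + len(norm_b),
               n_quantile_points=n_quantile_points)

    pool_a = pool_loci(norm_a, config.min_samples_per_locus)
    pool_b = pool_loci(norm_b, config.min_samples_per_locus)
    _log_stage(stage_log, "pool", pool="A", retained=len(pool_a.loci),
               excluded=pool_a.n_excluded)
    _log_stage(stage_log, "pool", pool="B", retained=len(pool_b.loci),
               excluded=pool_b.n_excluded)

    comparison = differential_map(pool_a.loci, pool_b.loci)
    _log_stage(stage_log, "differential", shared_loci=len(comparison))

    log_ratio = pd.Series(
        np.log2(comparison["ratio"].to_numpy()), index=comparison.index
    )
    flags = flag_extreme_loci(log_ratio, config.extreme_percentile)
    _log_stage(stage_log, "flags", n_total=flags.n_total,
               k_over=flags.k_over, k_under=flags.k_under)

    segments = build_segments(
        annotation, comparison.index, config.window_size, config.shift
    )
    scored = tag_and_test_segments(segments, flags, log_ratio, config)
    called = scored[scored["call"] != "none"].copy()
    deduped = deduplicate_segments(called)
    _log_stage(stage_log, "segments", n_segments=len(scored),
               n_called=len(called), n_after_dedup=len(deduped))

    single = single_gene_mode(log_ratio, annotation, config)
    _log_stage(stage_log, "single_gene", n_significant=len(single))

    chrom_summary = chromosome_mean_ratio(comparison, annotation)
    _log_stage(stage_log, "chromosome_summary", n_chromosomes=len(chrom_summary))

    return MapRunResult(
        pool_a=pool_a,
        pool_b=pool_b,
        comparison=comparison,
        segments=scored,
        called_segments=deduped,
        single_gene=single,
        chromosome_summary=chrom_summary,
        stage_log=stage_log,
    )


def write_bundle(
    result: MapRunResult, annotation: GenomeAnnotation, outdir: str | Path
) -> dict[str, Path]:
    """Write the standard output bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "locus_map": outdir / "locus_map.tsv",
        "segments": outdir / "segments.tsv",
        "called_segments": outdir / "called_segments.tsv",
        "segments_bed": outdir / "called_segments.bed",
        "single_gene": outdir / "single_gene.tsv",
        "chromosome_summary": outdir / "chromosome_summary.tsv",
        "run_log": outdir / "run_log.json",
    }
    tio.write_locus_map(result.comparison, annotation, paths["locus_map"])
    tio.write_segment_table(result.segments, paths["segments"])
    tio.write_segment_table(result.called_segments, paths["called_segments"])
    tio.write_segment_bed(result.called_segments, paths["segments_bed"])
    result.single_gene.to_csv(paths["single_gene"], sep="\t", index=False,
                              float_format="%.6g")
    result.chromosome_summary.to_csv(paths["chromosome_summary"], sep="\t",
                                     float_format="%.6g")
    with open(paths["run_log"], "w") as fh:
        json.dump(result.stage_log, fh, indent=1)
    return paths


def run_validation(qpcr_observed: pd.DataFrame | None = None) -> dict:
    """Validate the integrated map against qPCR observed ratios.

    With no argument, uses the packaged 13-gene fibroblast panel.
    Recomputes the expected ratio ER from the per-pool consensus values,
    checks it against the stored ER at 2 decimals, and correlates ER with
    the observed qPCR ratio OR.
    """
    panel = qpcr_observed if qpcr_observed is not None else load_validation_panel()
    recomputed = panel["eev_trisomic"] / panel["eev_euploid"]
    matches = int(
        sum(
            abs(_round2(r) - printed) < 1e-9
            for r, printed in zip(recomputed, panel["expected_ratio"])
        )
    )
    r, p, n = correlate_ratios(panel["expected_ratio"], panel["observed_ratio"])
    table = panel.copy()
    table["recomputed_er"] = recomputed
    return {
        "n_genes": len(panel),
        "er_matches_at_2dp": matches,
        "pearson_r": r,
        "pearson_p": p,
        "n_pairs": n,
        "table": table,
    }
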