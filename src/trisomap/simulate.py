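"""Ground-truthed synthetic multi-platform expression datasets.

The generator emulates the statistical structure the mapping pipeline
assumes for a trisomic vs. euploid meta-analysis:

* a genome of non-overlapping loci with realistic density (~6 loci per
  500 kb window) and lognormal gene sizes (median ~20 kb);
* a designated trisomic chromosome whose genes carry a mean 3:2 dosage
  ratio, with a configurable fraction of dosage-escaping genes (ratio 1);
* trans effects: non-trisomic genes pushed to ratio 1.5 or 0.67;
* optional planted over-/under-expressed segments (contiguous windows of
  genes at a given ratio) for segment-calling benchmarks;
* several array platforms of different feature counts, each covering a
  random subset of genes with 1-3 probes per gene, a per-probe affinity,
  a smooth monotone intensity-dependent multiplicative bias (what scaled
  quantile normalization must remove), and a declared emission scale
  (linear, ln, or log2);
* per-sample multiplicative lognormal noise.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneLocus, GenomeAnnotation, Platform
from .io import Sample, TRISOMIC, EUPLOID


@dataclass(frozen=True)
class PlatformSpec:
    """One synthetic platform: coverage, bias and emission format."""

    platform_id: str
    coverage: float = 0.9  # fraction of genome loci carried
    bias: float = 0.0  # exponent of the monotone intensity distortion
    log_format: str = "linear"  # emission scale: linear | ln | log2
    max_probes_per_gene: int = 3
    probe_sigma: float = 0.1  # per-probe affinity spread (log scale)
    unmapped_fraction: float = 0.02  # features with no gene assignment


@dataclass(frozen=True)
class PlantedSegment:
    """A contiguous genomic span whose member genes share a true ratio."""

    chromosome: str
    start: int
    length: int
    ratio: float

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic trisomy meta-analysis."""

    seed: int = 0
    n_chromosomes: int = 10
    genes_per_chromosome: int = 500
    chromosome_length: int = 40_000_000
    trisomic_chromosome: str = "21"
    dosage_factor: float = 1.5
    escape_fraction: float = 0.3
    trans_over: int = 25  # non-trisomic genes pushed to the dosage ratio
    trans_under: int = 25  # non-trisomic genes pushed to its reciprocal
    planted_segments: tuple[PlantedSegment, ...] = ()
    platforms: tuple[PlatformSpec, ...] = (
        PlatformSpec("array_hd", coverage=0.95, bias=0.10, log_format="linear"),
        PlatformSpec("array_log2", coverage=0.85, bias=-0.08, log_format="log2"),
        PlatformSpec("array_ln", coverage=0.70, bias=0.05, log_format="ln"),
    )
    samples_per_pool: int = 10
    noise_sigma: float = 0.2  # per-sample multiplicative lognormal sigma
    baseline_log_mean: float = math.log(100.0)
    between_gene_sigma: float = 1.0
    est_fraction: float = 0.15  # fraction of loci labelled as EST clusters
    #: platforms outside [5,000, 60,000] features are rejected; disable only
    #: for miniature test genomes where realistic platform sizes cannot fit
    enforce_platform_bounds: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValueError("escape_fraction must be in [0, 1]")
        if self.dosage_factor <= 0:
            raise ValueError("dosage_factor must be positive")

    @property
    def chromosome_names(self) -> list[str]:
        others = [str(i) for i in range(1, self.n_chromosomes)]
        return others + [self.trisomic_chromosome]


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene true ratios/classes and planted segments."""

    genes: pd.DataFrame  # index symbol; true_ratio, gene_class, chromosome
    planted_segments: tuple[PlantedSegment, ...]
    trisomic_chromosome: str


def generate_annotation(config: SyntheticConfig) -> GenomeAnnotation:
    """Place non-overlapping loci with lognormal sizes on each chromosome.

    Gene sizes are lognormal with median ~20 kb (mean ~28 kb, within a
    factor of a few of the ~67 kb mean protein-coding gene); gaps are
    drawn so the loci fill the chromosome without overlap.
    """
    rng = np.random.default_rng(config.seed)
    loci: list[GeneLocus] = []
    lengths: dict[str, int] = {}
    for chrom in config.chromosome_names:
        lengths[chrom] = config.chromosome_length
        n = config.genes_per_chromosome
        sizes = np.rint(
            np.exp(rng.normal(math.log(20_000), 0.8, size=n))
        ).astype(int)
        sizes = np.clip(sizes, 200, None)
        total = int(sizes.sum())
        slack = config.chromosome_length - total
        if slack <= n:
            raise ValueError(
                f"chromosome {chrom}: {n} genes of total size {total} do not "
                f"fit length {config.chromosome_length}"
            )
        gaps = rng.random(n + 1)
        gaps = np.rint(gaps / gaps.sum() * slack).astype(int)
        pos = 1
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = min(start + int(sizes[i]) - 1, config.chromosome_length)
            biotype = "est_cluster" if rng.random() < config.est_fraction else "known_gene"
            loci.append(
                GeneLocus(
                    symbol=f"G{chrom}_{i:04d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    biotype=biotype,
                )
            )
            pos = end + 1
    return GenomeAnnotation(loci, lengths)


def assign_truth(
    config: SyntheticConfig, annotation: GenomeAnnotation
) -> SyntheticTruth:
    """Assign a true A/B ratio and class to every locus."""
    rng = np.random.default_rng(config.seed + 1)
    ann = annotation.to_frame()
    symbols = ann["symbol"].to_numpy()
    chroms = ann["chromosome"].to_numpy()
    starts = ann["start"].to_numpy()
    ratio = np.ones(len(symbols))
    gene_class = np.array(["background"] * len(symbols), dtype=object)

    tri = chroms == config.trisomic_chromosome
    tri_idx = np.flatnonzero(tri)
    n_escape = int(round(config.escape_fraction * len(tri_idx)))
    escape_idx = rng.choice(tri_idx, size=n_escape, replace=False) if n_escape else []
    ratio[tri_idx] = config.dosage_factor
    gene_class[tri_idx] = "trisomic"
    ratio[escape_idx] = 1.0
    gene_class[escape_idx] = "escape"

    non_tri_idx = np.flatnonzero(~tri)
    n_trans = config.trans_over + config.trans_under
    if n_trans > len(non_tri_idx):
        raise ValueError("more trans-affected genes requested than available")
    trans_idx = rng.choice(non_tri_idx, size=n_trans, replace=False)
    over_idx = trans_idx[: config.trans_over]
    under_idx = trans_idx[config.trans_over:]
    ratio[over_idx] = config.dosage_factor
    gene_class[over_idx] = "trans_over"
    ratio[under_idx] = 1.0 / config.dosage_factor
    gene_class[under_idx] = "trans_under"

    for planted in config.planted_segments:
        member = (
            (chroms == planted.chromosome)
            & (starts >= planted.start)
            & (starts <= planted.end)
        )
        ratio[member] = planted.ratio
        gene_class[member] = "planted"

    genes = pd.DataFrame(
        {"true_ratio": ratio, "gene_class": gene_class, "chromosome": chroms},
        index=pd.Index(symbols, name="symbol"),
    )
    return SyntheticTruth(
        genes=genes,
        planted_segments=tuple(config.planted_segments),
        trisomic_chromosome=config.trisomic_chromosome,
    )


def choose_planted_segments(
    annotation: GenomeAnnotation,
    n_segments: int,
    *,
    length: int = 500_000,
    ratio: float = 3.0,
    min_genes: int = 4,
    exclude_chromosomes: Sequence[str] = (),
    seed: int = 0,
) -> tuple[PlantedSegment, ...]:
    """Pick non-overlapping spans each holding at least ``min_genes`` loci."""
    rng = np.random.default_rng(seed)
    ann = annotation.to_frame()
    candidates = []
    for chrom, clen in annotation.chromosome_lengths.items():
        if chrom in exclude_chromosomes:
            continue
        starts = ann.loc[ann["chromosome"] == chrom, "start"].to_numpy()
        for ws in range(1, clen - length + 2, length):
            n = int(np.searchsorted(starts, ws + length - 1, side="right")
                    - np.searchsorted(starts, ws, side="left"))
            if n >= min_genes:
                candidates.append(PlantedSegment(chrom, ws, length, ratio))
    if len(candidates) < n_segments:
        raise ValueError(
            f"only {len(candidates)} candidate spans with >= {min_genes} loci"
        )
    picked = rng.choice(len(candidates), size=n_segments, replace=False)
    return tuple(candidates[i] for i in sorted(picked))


def _platform_from_spec(
    spec: PlatformSpec,
    symbols: np.ndarray,
    rng: np.random.Generator,
    enforce_size: bool = True,
) -> tuple[Platform, pd.DataFrame]:
    """Build the probe universe for one platform.

    Returns the Platform plus a probe table (probe_id, symbol, affinity)
    where unmapped filler probes have symbol "" and affinity NaN.
    """
    n_cov = int(round(spec.coverage * len(symbols)))
    covered = rng.choice(symbols, size=n_cov, replace=False)
    covered.sort()
    n_probes = rng.integers(1, spec.max_probes_per_gene + 1, size=n_cov)
    probe_ids, probe_syms = [], []
    for sym, k in zip(covered, n_probes):
        for j in range(k):
            probe_ids.append(f"{spec.platform_id}:{sym}:{j}")
            probe_syms.append(sym)
    affinity = np.exp(rng.normal(0.0, spec.probe_sigma, size=len(probe_ids)))
    n_unmapped = int(round(spec.unmapped_fraction * len(probe_ids)))
    for j in range(n_unmapped):
        probe_ids.append(f"{spec.platform_id}:ctrl:{j}")
        probe_syms.append("")
    affinity = np.concatenate([affinity, np.full(n_unmapped, np.nan)])
    table = pd.DataFrame(
        {"probe_id": probe_ids, "symbol": probe_syms, "affinity": affinity}
    )
    probe_map = {
        p: s for p, s in zip(table["probe_id"], table["symbol"]) if s != ""
    }
    platform = Platform(
        platform_id=spec.platform_id,
        probe_map=probe_map,
        probes=set(table["probe_id"]),
        enforce_size=enforce_size,
    )
    return platform, table


def _apply_bias(values: np.ndarray, beta: float) -> np.ndarray:
    """Smooth monotone intensity-dependent distortion: v -> m*(v/m)^(1+beta)."""
    if beta == 0.0:
        return values
    m = np.median(values)
    return m * (values / m) ** (1.0 + beta)


def simulate_pools(
    config: SyntheticConfig, annotation: GenomeAnnotation | None = None
) -> tuple[list[Sample], list[Sample], dict[str, Platform], SyntheticTruth]:
    """Simulate both sample pools across all configured platforms.

    Per gene g: baseline b_g ~ lognormal(baseline_log_mean,
    between_gene_sigma); the trisomic-pool mean is b_g x true_ratio_g.  A
    sample value for probe p of gene g is pool_mean_g x affinity_p x
    lognormal(0, noise_sigma), passed through the platform's monotone bias
    curve and emitted in the platform's declared scale.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    truth = assign_truth(config, annotation)
    rng = np.random.default_rng(config.seed + 2)
    symbols = truth.genes.index.to_numpy()
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.between_gene_sigma, len(symbols))
    )
    pool_mean = {
        TRISOMIC: baseline * truth.genes["true_ratio"].to_numpy(),
        EUPLOID: baseline,
    }
    mean_by_symbol = {
        cond: dict(zip(symbols, means)) for cond, means in pool_mean.items()
    }
    platforms: dict[str, Platform] = {}
    tables: dict[str, pd.DataFrame] = {}
    for spec in config.platforms:
        platform, table = _platform_from_spec(
            spec, symbols, rng, enforce_size=config.enforce_platform_bounds
        )
        platforms[spec.platform_id] = platform
        tables[spec.platform_id] = table
    specs = list(config.platforms)
    samples_a: list[Sample] = []
    samples_b: list[Sample] = []
    # samples_per_pool is the pool's total size; samples are distributed
    # round-robin over the platforms, as in a multi-study meta-analysis
    for cond, bucket in ((TRISOMIC, samples_a), (EUPLOID, samples_b)):
        for s in range(config.samples_per_pool):
            spec = specs[s % len(specs)]
            table = tables[spec.platform_id]
            mapped = table[table["symbol"] != ""]
            filler = table[table["symbol"] == ""]
            means = mapped["symbol"].map(mean_by_symbol[cond]).to_numpy()
            base_probe = means * mapped["affinity"].to_numpy()
            noise = np.exp(
                rng.normal(0.0, config.noise_sigma, size=len(base_probe))
            )
            values = _apply_bias(base_probe * noise, spec.bias)
            filler_values = np.exp(
                rng.normal(config.baseline_log_mean, 1.0, size=len(filler))
            )
            all_values = np.concatenate([values, filler_values])
            probe_index = pd.Index(
                list(mapped["probe_id"]) + list(filler["probe_id"]),
                name="probe_id",
            )
            if spec.log_format == "ln":
                emitted = np.log(all_values)
            elif spec.log_format == "log2":
                emitted = np.log2(all_values)
            else:
                emitted = all_values
            tag = "T" if cond == TRISOMIC else "E"
            bucket.append(
                Sample(
                    sample_id=f"{spec.platform_id}_{tag}{s:02d}",
                    platform_id=spec.platform_id,
                    condition=cond,
                    tissue="synthetic",
                    scale=spec.log_format,
                    values=pd.Series(emitted, index=probe_index, dtype=float),
                )
            )
    return samples_a, samples_b, platforms, truth


def simulate_ratio_map(
    truth: SyntheticTruth, noise_sigma: float = 0.2, seed: int = 0
) -> pd.Series:
    """Observed per-locus A/B ratios: true ratio x lognormal(0, sigma) noise.

    A lightweight stand-in for the full multi-platform pipeline, used for
    segment-calling benchmarks where only the ratio map matters.
    """
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, noise_sigma, size=len(truth.genes)))
    return pd.Series(
        truth.genes["true_ratio"].to_numpy() * noise,
        index=truth.genes.index,
        name="ratio",
    )


def truth_report(
    truth: SyntheticTruth,
    called_segments: pd.DataFrame,
    comparison: pd.DataFrame | None = None,
) -> dict:
    """Score pipeline output against the generator's ground truth.

    Segment sensitivity counts a planted segment as found when a called
    segment of the same direction overlaps it by at least one base;
    precision is the fraction of calls overlapping a planted segment of
    matching direction (None when there are no calls).  If a comparison
    map is given, per-class ratio bias and RMSE are reported too.
    """
    planted = truth.planted_segments
    found = 0
    true_calls = 0
    for p in planted:
        direction = "over" if p.ratio > 1 else "under"
        hit = _overlapping_calls(called_segments, p, direction)
        if hit:
            found += 1
    for _, row in called_segments.iterrows():
        direction = row["call"]
        if any(
            _overlaps(row, p)
            and direction == ("over" if p.ratio > 1 else "under")
            for p in planted
        ):
            true_calls += 1
    n_calls = len(called_segments)
    report = {
        "n_planted": len(planted),
        "n_called": n_calls,
        "sensitivity": (found / len(planted)) if planted else None,
        "precision": (true_calls / n_calls) if n_calls else None,
        "false_calls": n_calls - true_calls,
    }
    if comparison is not None:
        per_class = {}
        joined = comparison.join(truth.genes[["true_ratio", "gene_class"]], how="inner")
        if len(joined) != len(comparison):
            raise ValueError("comparison loci not all present in truth (mismatched run)")
        for cls, grp in joined.groupby("gene_class"):
            err = grp["ratio"] - grp["true_ratio"]
            per_class[cls] = {
                "n": len(grp),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err ** 2).mean())),
                "median_ratio": float(grp["ratio"].median()),
            }
        report["ratio_by_class"] = per_class
    return report


def _overlaps(row: pd.Series, planted: PlantedSegment) -> bool:
    return (
        row["chromosome"] == planted.chromosome
        and row["start"] <= planted.end
        and row["end"] >= planted.start
    )


def _overlapping_calls(
    called: pd.DataFrame, planted: PlantedSegment, direction: str
) -> bool:
    for _, row in called.iterrows():
        if row["call"] == direction and _overlaps(row, planted):
            return True
    return False


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(
    outdir: str | Path,
    config: SyntheticConfig,
    annotation: GenomeAnnotation,
    samples_a: list[Sample],
    samples_b: list[Sample],
    platforms: dict[str, Platform],
    truth: SyntheticTruth,
) -> None:
    """Write the simulated dataset in the same TSV formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_df = annotation.to_frame()
    ann_df.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)
    for pid, platform in platforms.items():
        rows = [
            (probe, platform.probe_map.get(probe, ""))
            for probe in sorted(platform.probes)
        ]
        pd.DataFrame(rows, columns=["probe_id", "gene_symbol"]).to_csv(
            outdir / f"platform_{pid}.tsv", sep="\t", index=False
        )
    manifest = []
    for sample in samples_a + samples_b:
        fname = f"sample_{sample.sample_id}.tsv"
        sample.values.rename("value").to_csv(
            outdir / fname, sep="\t", header=False, float_format="%.10g"
        )
        manifest.append(
            {
                "sample_id": sample.sample_id,
                "path": fname,
                "platform": sample.platform_id,
                "condition": sample.condition,
                "scale": sample.scale,
                "tissue": sample.tissue,
            }
        )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "pool_a": [m for m in manifest if m["condition"] == TRISOMIC],
                "pool_b": [m for m in manifest if m["condition"] == EUPLOID],
                "annotation": "gene_annotation.tsv",
                "platforms": {
                    pid: f"platform_{pid}.tsv" for pid in sorted(platforms)
                },
            },
            fh,
            sort_keys=False,
        )
    truth.genes.reset_index().to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    planted_df = pd.DataFrame(
        [
            (p.chromosome, p.start, p.end, p.ratio)
            for p in truth.planted_segments
        ],
        columns=["chromosome", "start", "end", "ratio"],
    )
    planted_df.to_csv(outdir / "truth_segments.tsv", sep="\t", index=False)
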