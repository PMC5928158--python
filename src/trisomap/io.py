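"""Readers and writers for the pipeline's tabular formats.

Expression tables are two-column TSV (probe id, intensity); the intensity
scale (linear, natural log, or log2) is declared per sample, not sniffed.
Probes without a value are omitted at read time — an absent measurement is
treated as "not measured", never as zero.

Output tables mirror the supplementary-table shape of published
transcriptome maps (per-locus consensus values with pool means, ratio and
dosage band), plus BED5 for genome-browser display of called segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (
    GenomeAnnotation,
    GeneLocus,
    Platform,
    PlatformSizeError,
    MIN_PLATFORM_FEATURES,
    MAX_PLATFORM_FEATURES,
)

log = logging.getLogger(__name__)

SCALES = ("linear", "ln", "log2")

TRISOMIC = "trisomic"
EUPLOID = "euploid"


@dataclass
class Sample:
    """One array's probe-level intensities with declared scale and condition."""

    sample_id: str
    platform_id: str
    condition: str = TRISOMIC
    tissue: str = ""
    gender: str = "unknown"
    scale: str = "linear"
    values: "pd.Series[float]" = field(default_factory=lambda: pd.Series(dtype=float))
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")


def read_expression_table(
    path: str | Path,
    scale: str,
    *,
    condition: str = TRISOMIC,
    tissue: str = "",
    gender: str = "unknown",
    sample_id: str | None = None,
    platform_id: str = "",
) -> Sample:
    """Parse a two-column tab-delimited expression table into a :class:`Sample`.

    A header row is auto-detected (non-numeric second field on the first
    line).  Blank or missing values are omitted and counted; a duplicated
    probe id is an error because the input is then ambiguous.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    probes: list[str] = []
    values: list[float] = []
    seen: set[str] = set()
    n_missing = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            probe, value = fields
            if lineno == 1 and value.strip() != "" and not _is_number(value):
                continue  # header row
            if probe in seen:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            seen.add(probe)
            if value.strip() == "":
                n_missing += 1
                continue
            if not _is_number(value):
                raise ValueError(f"{path}:{lineno}: non-numeric value {value!r}")
            probes.append(probe)
            values.append(float(value))
    if n_missing:
        log.info("%s: omitted %d probes without an expression value", path, n_missing)
    return Sample(
        sample_id=sample_id,
        platform_id=platform_id,
        condition=condition,
        tissue=tissue,
        gender=gender,
        scale=scale,
        values=pd.Series(values, index=pd.Index(probes, name="probe_id"), dtype=float),
        n_missing=n_missing,
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def linearize(sample: Sample) -> Sample:
    """Undo a declared log transform so every sample is on the linear scale."""
    if sample.scale == "linear":
        return replace(sample, values=sample.values.copy())
    if sample.scale == "ln":
        values = np.exp(sample.values)
    elif sample.scale == "log2":
        values = np.exp2(sample.values)
    else:  # pragma: no cover - guarded by Sample.__post_init__
        raise ValueError(f"unknown scale {sample.scale!r}")
    return replace(sample, values=values, scale="linear")


@dataclass
class ResolvedSample:
    """Per-sample (locus symbol, value) records plus drop accounting.

    ``n_emitted + n_unmapped + n_missing`` always equals the platform's
    feature count, so no probe goes silently unaccounted for.
    """

    sample_id: str
    condition: str
    records: pd.DataFrame  # columns: symbol, value
    n_emitted: int
    n_unmapped: int  # no symbol on the platform, or symbol absent from genome
    n_missing: int  # platform probes without a measurement in this sample


def resolve_probes(
    sample: Sample, platform: Platform, annotation: GenomeAnnotation
) -> ResolvedSample:
    """Convert probe-level intensities to locus-symbol records.

    Every probe with a platform-mapped symbol that is present in the genome
    annotation yields one record; multiple probes for the same symbol yield
    multiple records (collapsing to a single consensus value happens once,
    at pooling).  Requires a linearized sample.
    """
    if sample.scale != "linear":
        raise ValueError(f"sample {sample.sample_id} must be linearized first")
    if sample.platform_id and sample.platform_id != platform.platform_id:
        raise ValueError(
            f"sample {sample.sample_id} declares platform {sample.platform_id!r}, "
            f"got platform {platform.platform_id!r}"
        )
    foreign = set(sample.values.index) - platform.probes
    if foreign:
        raise ValueError(
            f"sample {sample.sample_id}: {len(foreign)} probes not on platform "
            f"{platform.platform_id} (e.g. {sorted(foreign)[:3]})"
        )
    probe_ids = sample.values.index
    symbols = probe_ids.map(platform.probe_map)  # NaN where unmapped
    in_genome = pd.Series(
        [s in annotation if isinstance(s, str) else False for s in symbols],
        index=probe_ids,
    )
    keep = in_genome.to_numpy()
    records = pd.DataFrame(
        {
            "symbol": symbols.to_numpy()[keep],
            "value": sample.values.to_numpy()[keep],
        }
    )
    n_emitted = len(records)
    n_measured = len(sample.values)
    n_missing = platform.feature_count - n_measured
    n_unmapped = n_measured - n_emitted
    if n_unmapped:
        log.info(
            "%s: dropped %d probes without an annotated locus symbol",
            sample.sample_id,
            n_unmapped,
        )
    return ResolvedSample(
        sample_id=sample.sample_id,
        condition=sample.condition,
        records=records,
        n_emitted=n_emitted,
        n_unmapped=n_unmapped,
        n_missing=n_missing,
    )


# ---------------------------------------------------------------------------
# annotation tables


def read_platform_annotation(path: str | Path, platform_id: str | None = None) -> Platform:
    """Read a probe→gene-symbol TSV; blank symbols mean "probe maps to nothing".

    Platforms with a feature count outside [5,000, 60,000] are rejected as
    analyzing an atypical number of genes.
    """
    path = Path(path)
    if platform_id is None:
        platform_id = path.stem
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        names=["probe_id", "gene_symbol"], header=None, skiprows=_header_rows(path),
    )
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    probes = set(df["probe_id"])
    mapped = df[df["gene_symbol"].str.strip() != ""]
    probe_map = dict(zip(mapped["probe_id"], mapped["gene_symbol"]))
    return Platform(platform_id=platform_id, probe_map=probe_map, probes=probes)


def _header_rows(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if first and first[0].strip().lower() in ("probe_id", "probe", "id", "symbol"):
        return 1
    return 0


def read_gene_annotation(
    path: str | Path, chromosome_lengths: Mapping[str, int] | None = None
) -> GenomeAnnotation:
    """Read a locus table TSV: symbol, chromosome, start, end, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chromosome": str})
    required = {"symbol", "chromosome", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "biotype" not in df.columns:
        df["biotype"] = "known_gene"
    return GenomeAnnotation.from_frame(df, chromosome_lengths)


def write_gene_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables


def write_locus_map(
    comparison: pd.DataFrame, annotation: GenomeAnnotation, path: str | Path
) -> None:
    """Write the per-locus differential map in supplementary-table shape."""
    df = comparison.copy()
    ann = annotation.to_frame().set_index("symbol")
    df = df.join(ann[["chromosome", "start", "end"]], how="left")
    cols = [
        "chromosome", "start", "end",
        "meanA", "nA_values", "nA_samples",
        "meanB", "nB_values", "nB_samples",
        "ratio", "band", "percentile",
    ]
    cols = [c for c in cols if c in df.columns]
    out = df[cols].reset_index(names="symbol")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_segment_table(segments: pd.DataFrame, path: str | Path) -> None:
    df = segments.copy()
    if "loci" in df.columns:
        df["loci"] = df["loci"].map(lambda syms: ",".join(syms))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_segment_bed(segments: pd.DataFrame, path: str | Path) -> None:
    """Write called segments as BED5.

    Internal coordinates are 1-based inclusive; BED is 0-based half-open,
    so start becomes start-1 and end is unchanged.  The name column is the
    call direction and the score column is -log10(q), capped at 1000.
    """
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            q = getattr(row, "q", None)
            if q is None or not np.isfinite(q) or q <= 0:
                score = 1000.0
            else:
                score = min(-math.log10(q), 1000.0)
            fh.write(
                f"{row.chromosome}\t{row.start - 1}\t{row.end}\t"
                f"{row.call}\t{score:.6g}\n"
            )


def write_gene_list(symbols: list[str], path: str | Path) -> None:
    """One symbol per line, for external enrichment tools."""
    with open(path, "w") as fh:
        for symbol in symbols:
            fh.write(symbol + "\n")
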