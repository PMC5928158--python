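"""Per-locus consensus values, differential maps and dosage bands.

Each locus's consensus value in a pool is the plain arithmetic mean of all
normalized (probe, sample) records available for it; loci supported by
fewer than ``min_samples`` distinct biological samples are excluded.  The
differential map is the per-locus ratio of pool means (A/B, by convention
trisomic over euploid), classified into dosage bands: a full extra copy of
a chromosome predicts a 3:2 (1.5) ratio for its genes and trans effects
may push other genes toward 3:2 or 2:3 (0.67); allowing for natural
variation the bands are over >= 1.30, neutral 1.29-0.77, under <= 0.76,
with the ratio compared after rounding to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, EST_CLUSTER
from .normalize import NormalizedSample

#: Gene-dosage model constants: expected ratios under a 3:2 / 2:3 dosage
#: effect and the band boundaries extended for natural variation.
EXPECTED_OVER = 1.5
EXPECTED_UNDER = 0.67
BAND_OVER = 1.30
BAND_UNDER = 0.76

DEFAULT_MIN_SAMPLES = 3


@dataclass
class PoolResult:
    """Consensus per-locus summaries for one pool."""

    loci: pd.DataFrame  # index symbol; mean_value, n_values, n_samples, percentile
    n_excluded: int  # loci dropped for insufficient biological samples


def pool_loci(
    samples: list[NormalizedSample], min_samples: int = DEFAULT_MIN_SAMPLES
) -> PoolResult:
    """Collapse normalized records into per-locus consensus means.

    The mean is taken over all (probe, sample) records equally — a gene
    measured by three probes on one platform contributes three records.
    ``n_samples`` counts distinct biological samples; loci below
    ``min_samples`` are excluded from all downstream maps.  Percentiles are
    mean-rank percentiles of the consensus mean among retained loci.
    """
    if not samples:
        raise ValueError("pool_loci: empty sample list")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    frames = []
    for s in samples:
        df = s.records[["symbol", "value"]].copy()
        df["sample_id"] = s.sample_id
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    grouped = records.groupby("symbol", sort=True)
    summary = pd.DataFrame(
        {
            "mean_value": grouped["value"].mean(),
            "n_values": grouped["value"].size(),
            "n_samples": grouped["sample_id"].nunique(),
        }
    )
    retained = summary[summary["n_samples"] >= min_samples].copy()
    n_excluded = len(summary) - len(retained)
    if len(retained):
        ranks = retained["mean_value"].rank(method="average")
        retained["percentile"] = 100.0 * ranks / len(retained)
    else:
        retained["percentile"] = pd.Series(dtype=float)
    return PoolResult(loci=retained, n_excluded=n_excluded)


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (printed-table convention)."""
    return math.floor(x * 100.0 + 0.5) / 100.0


def classify_dosage_band(ratio: float) -> str:
    """Classify an A/B ratio as over (>=1.30), under (<=0.76) or neutral.

    The comparison uses the ratio rounded to two decimals, matching the
    printed band boundaries (1.29 and 1.30 are adjacent only at that
    precision).
    """
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    r = _round2(ratio)
    if r >= BAND_OVER:
        return "over"
    if r <= BAND_UNDER:
        return "under"
    return "neutral"


def differential_map(pool_a: pd.DataFrame, pool_b: pd.DataFrame) -> pd.DataFrame:
    """Per-locus A/B comparison over loci present in both pools.

    Accepts the ``loci`` frames from :func:`pool_loci` (or any frames with
    a ``mean_value`` column indexed by symbol).  Returns one row per shared
    locus with pool means, counts, ratio and dosage band.
    """
    shared = pool_a.index.intersection(pool_b.index)
    if len(shared) == 0:
        raise ValueError("no loci shared between the two pools")
    a = pool_a.loc[shared]
    b = pool_b.loc[shared]
    comp = pd.DataFrame(index=shared)
    comp.index.name = "symbol"
    comp["meanA"] = a["mean_value"]
    comp["meanB"] = b["mean_value"]
    for col, src in (("nA_values", a), ("nB_values", b)):
        if "n_values" in src.columns:
            comp[col] = src["n_values"]
    for col, src in (("nA_samples", a), ("nB_samples", b)):
        if "n_samples" in src.columns:
            comp[col] = src["n_samples"]
    comp["ratio"] = comp["meanA"] / comp["meanB"]
    comp["band"] = [classify_dosage_band(r) for r in comp["ratio"]]
    if "percentile" in a.columns:
        comp["percentile"] = a["percentile"]
    return comp


def export_band_gene_lists(
    comparison: pd.DataFrame,
    annotation: GenomeAnnotation | None = None,
    exclude_est: bool = True,
) -> tuple[list[str], list[str]]:
    """Gene lists for external enrichment tools: (over, under).

    EST clusters — loci without full gene characterization — are removed
    when ``exclude_est`` is set (requires the annotation for biotypes).
    """
    over = [s for s in comparison.index[comparison["band"] == "over"]]
    under = [s for s in comparison.index[comparison["band"] == "under"]]
    if exclude_est:
        if annotation is None:
            raise ValueError("annotation required to exclude EST clusters")
        over = [s for s in over if annotation[s].biotype != EST_CLUSTER]
        under = [s for s in under if annotation[s].biotype != EST_CLUSTER]
    return over, under
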