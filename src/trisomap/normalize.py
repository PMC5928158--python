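"""Two-stage normalization for cross-platform integration.

Stage 1 (intra-sample): non-positive intensities are thresholded to 95% of
the sample's minimum positive value, then every value is expressed as a
percentage of the sample mean ("global normalization"), so each sample has
mean exactly 100 regardless of its platform's dynamic range.

Stage 2 (inter-sample): scaled quantile normalization.  Classical quantile
normalization requires every sample to carry the same number of features;
platforms here differ by an order of magnitude.  The scaled variant works
on a fixed-resolution quantile grid: each sample's empirical quantile
function is evaluated at ``n_points`` equally spaced probabilities, the
reference is the pointwise mean of those curves over all samples (both
pools jointly), and each value is mapped to the reference quantile at its
own fractional within-sample rank.  When all samples share a feature count
equal to ``n_points`` this reduces exactly to classical quantile
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_N_QUANTILE_POINTS = 1001
DEFAULT_THRESHOLD_FACTOR = 0.95


@dataclass
class NormalizedSample:
    """Per-sample (symbol, value) records in percent-of-mean units."""

    sample_id: str
    condition: str
    records: pd.DataFrame  # columns: symbol, value


@dataclass
class QuantileReference:
    """Reference quantile curve shared by all samples in an analysis."""

    grid: np.ndarray  # nondecreasing, length n_points

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ValueError("reference grid must be a 1-D vector of >= 2 points")
        if np.any(np.diff(self.grid) < 0):
            raise ValueError("reference grid must be nondecreasing")

    @property
    def n_points(self) -> int:
        return len(self.grid)

    @property
    def probabilities(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)


def threshold_nonpositive(
    values: np.ndarray, factor: float = DEFAULT_THRESHOLD_FACTOR
) -> np.ndarray:
    """Replace values <= 0 by ``factor`` x the sample's minimum positive value.

    A zero intensity cannot enter a ratio; treating it as "below detection"
    and flooring it just under the smallest detected value keeps ratios
    defined while preserving strong over-expression signals.
    """
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("sample has no positive values; cannot threshold")
    floor = factor * positive.min()
    return np.where(values > 0, values, floor)


def intra_sample_normalize(records: pd.DataFrame, *, sample_id: str = "",
                           condition: str = "") -> NormalizedSample:
    """Express each value as percent of the sample mean (output mean = 100)."""
    if len(records) == 0:
        raise ValueError("cannot normalize an empty sample")
    values = records["value"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("non-positive values present; threshold first")
    normalized = 100.0 * values / values.mean()
    out = pd.DataFrame({"symbol": records["symbol"].to_numpy(), "value": normalized})
    return NormalizedSample(sample_id=sample_id, condition=condition, records=out)


def build_quantile_reference(
    samples: list[NormalizedSample], n_points: int = DEFAULT_N_QUANTILE_POINTS
) -> QuantileReference:
    """Pointwise mean of per-sample empirical quantile curves.

    The reference must span the full analysis (both pools jointly):
    per-pool references would erase exactly the pool-level shifts the
    differential map measures.
    """
    if not samples:
        raise ValueError("need at least one sample to build a reference")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    probs = np.linspace(0.0, 1.0, n_points)
    curves = []
    for sample in samples:
        values = sample.records["value"].to_numpy(dtype=float)
        if values.size < 2:
            raise ValueError(
                f"sample {sample.sample_id}: need >= 2 values for quantiles"
            )
        curves.append(np.quantile(values, probs))  # linear interpolation
    grid = np.mean(curves, axis=0)
    grid = np.maximum.accumulate(grid)  # guard against float jitter
    return QuantileReference(grid=grid)


def scaled_quantile_normalize(
    sample: NormalizedSample, ref: QuantileReference
) -> NormalizedSample:
    """Map each value to the reference quantile at its fractional rank.

    Ranks use the mean-rank convention for ties, so tied input values stay
    tied; within-sample rank order is preserved by monotonicity of the grid.
    """
    values = sample.records["value"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(f"sample {sample.sample_id}: need >= 2 values")
    ranks = rankdata(values, method="average")  # 1..n, ties share mean rank
    positions = (ranks - 1.0) / (values.size - 1.0)
    mapped = np.interp(positions, ref.probabilities, ref.grid)
    out = pd.DataFrame({"symbol": sample.records["symbol"].to_numpy(), "value": mapped})
    return NormalizedSample(
        sample_id=sample.sample_id, condition=sample.condition, records=out
    )


def normalize_samples(
    resolved: list, *, n_points: int = DEFAULT_N_QUANTILE_POINTS,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> list[NormalizedSample]:
    """Full two-stage normalization for a joint analysis.

    Takes :class:`trisomap.io.ResolvedSample` objects (records with locus
    symbols), thresholds and globally normalizes each, builds the joint
    quantile reference, and maps every sample onto it.
    """
    intra = []
    for rs in resolved:
        records = rs.records.copy()
        records["value"] = threshold_nonpositive(
            records["value"].to_numpy(), threshold_factor
        )
        intra.append(
            intra_sample_normalize(
                records, sample_id=rs.sample_id, condition=rs.condition
            )
        )
    ref = build_quantile_reference(intra, n_points)
    return [scaled_quantile_normalize(s, ref) for s in intra]
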