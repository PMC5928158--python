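"""qPCR-side validation arithmetic: 2^-ddCt ratios and expected-vs-observed r.

Relative quantification by the 2^-ddCt method: for each pool,
dCt = Ct(target) - Ct(reference) (mean over reference genes when several
are used); ddCt = dCt(test) - dCt(control); the observed expression ratio
of the test condition over the control is 2^(-ddCt).  One PCR cycle of
difference corresponds to a two-fold expression change.

The map-level validation compares, gene by gene, the expected ratio ER
(pool-A consensus mean over pool-B consensus mean from the integrated map)
with the observed ratio OR from qPCR, summarized by the Pearson
correlation.  A 13-gene fibroblast validation panel spanning strong
over-expression (ratio >= 2), dosage-consistent ratios (1.4-1.8), a
neutral control and under-expressed genes is packaged as a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrMeasurement:
    """Mean threshold cycles for one target gene in both pools."""

    gene: str
    ct_target_test: float
    ct_target_control: float
    ct_reference_test: Mapping[str, float] = field(default_factory=dict)
    ct_reference_control: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct in (self.ct_target_test, self.ct_target_control,
                   *self.ct_reference_test.values(),
                   *self.ct_reference_control.values()):
            if not (np.isfinite(ct) and ct > 0):
                raise ValueError(f"{self.gene}: Ct values must be finite and > 0")


def delta_delta_ct(m: QpcrMeasurement) -> float:
    """Observed test/control expression ratio, 2^-ddCt.

    Multiple reference genes are combined by the arithmetic mean of their
    Ct values (equivalently, the geometric mean of their relative
    quantities).
    """
    if not m.ct_reference_test or not m.ct_reference_control:
        raise ValueError(f"{m.gene}: at least one reference gene Ct per pool required")
    if set(m.ct_reference_test) != set(m.ct_reference_control):
        raise ValueError(f"{m.gene}: reference genes differ between pools")
    ref_test = float(np.mean(list(m.ct_reference_test.values())))
    ref_control = float(np.mean(list(m.ct_reference_control.values())))
    d_test = m.ct_target_test - ref_test
    d_control = m.ct_target_control - ref_control
    ddct = d_test - d_control
    return float(2.0 ** (-ddct))


def correlate_ratios(
    expected: "np.ndarray | list[float] | pd.Series",
    observed: "np.ndarray | list[float] | pd.Series",
) -> tuple[float, float, int]:
    """Pearson r between expected and observed ratios, with two-sided p.

    The p-value comes from the t distribution with n-2 degrees of freedom.
    Requires n >= 3 and non-degenerate variance in both columns.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected and observed must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the ratio columns")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue), n


def load_validation_panel() -> pd.DataFrame:
    """The packaged 13-gene fibroblast validation panel.

    Columns: gene, eev_trisomic, eev_euploid (per-pool consensus expression
    values in percent-of-mean units), expected_ratio (map A/B ratio),
    observed_ratio (qPCR 2^-ddCt).
    """
    ref = resources.files("trisomap.data").joinpath("fibroblast_validation_panel.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def read_qpcr_table(
    path: str | Path, reference_genes: tuple[str, ...] = ("GAPDH", "B2M")
) -> list[QpcrMeasurement]:
    """Read a long-format qPCR TSV (gene, pool, replicate, ct).

    Pools are labelled ``test``/``control``.  Technical replicates are
    averaged to a mean Ct per (gene, pool) before the ddCt arithmetic.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "pool": str})
    required = {"gene", "pool", "ct"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    mean_ct = df.groupby(["gene", "pool"])["ct"].mean()
    refs = {
        pool: {g: float(mean_ct[g, pool]) for g in reference_genes}
        for pool in ("test", "control")
    }
    measurements = []
    for gene in df["gene"].unique():
        if gene in reference_genes:
            continue
        measurements.append(
            QpcrMeasurement(
                gene=gene,
                ct_target_test=float(mean_ct[gene, "test"]),
                ct_target_control=float(mean_ct[gene, "control"]),
                ct_reference_test=refs["test"],
                ct_reference_control=refs["control"],
            )
        )
    return measurements
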