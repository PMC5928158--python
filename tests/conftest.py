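import numpy as np
import pandas as pd
import pytest

from trisomap.annotation import GeneLocus, GenomeAnnotation, Platform
from trisomap.normalize import NormalizedSample


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Six loci on two chromosomes, including one EST cluster."""
    loci = [
        GeneLocus("GENE1", "1", 100, 5_000),
        GeneLocus("GENE2", "1", 300_000, 320_000),
        GeneLocus("GENE3", "1", 600_000, 640_000),
        GeneLocus("EST1", "1", 900_000, 905_000, biotype="est_cluster"),
        GeneLocus("GENE4", "2", 50_000, 70_000),
        GeneLocus("GENE5", "2", 400_000, 420_000),
    ]
    return GenomeAnnotation(loci, {"1": 1_000_000, "2": 1_000_000})


@pytest.fixture
def toy_platform() -> Platform:
    probe_map = {
        "p1": "GENE1", "p2": "GENE1", "p3": "GENE2", "p4": "GENE3",
        "p5": "EST1", "p6": "GENE4", "p7": "GENE5", "p8": "NOT_IN_GENOME",
    }
    return Platform(
        platform_id="toy",
        probe_map=probe_map,
        probes=set(probe_map) | {"p9_unmapped"},
        enforce_size=False,
    )


def make_normalized(sample_id: str, condition: str, pairs) -> NormalizedSample:
    """Helper: NormalizedSample from a list of (symbol, value) pairs."""
    df = pd.DataFrame(pairs, columns=["symbol", "value"])
    return NormalizedSample(sample_id=sample_id, condition=condition, records=df)


def classical_quantile_normalize(columns: list[np.ndarray]) -> list[np.ndarray]:
    """Independent oracle: textbook quantile normalization, equal-length samples.

    Reference = mean of sorted columns; each value is assigned the
    reference entry at its rank (ties get the mean of the tied reference
    entries).
    """
    sorted_cols = np.sort(np.stack(columns), axis=1)
    reference = sorted_cols.mean(axis=0)
    out = []
    for col in columns:
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(len(col), dtype=float)
        ranks[order] = np.arange(len(col))
        # average reference over tied input values
        mapped = np.empty(len(col))
        values, inverse = np.unique(col, return_inverse=True)
        for u in range(len(values)):
            idx = np.flatnonzero(inverse == u)
            mapped[idx] = reference[ranks[idx].astype(int)].mean()
        out.append(mapped)
    return out
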