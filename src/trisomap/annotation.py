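"""Genomic annotation containers: gene loci, platforms, and the genome table.

A transcriptome map positions per-locus expression values on genomic
coordinates.  Loci are either characterized genes or EST clusters; both are
carried through the whole pipeline and distinguished only by ``biotype``
(EST clusters are excluded from enrichment exports, nothing else).

Coordinates are 1-based and inclusive throughout the package; the single
conversion point to 0-based half-open intervals is the BED writer in
:mod:`trisomap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}

KNOWN_GENE = "known_gene"
EST_CLUSTER = "est_cluster"

#: Inclusive bounds on the number of features an array platform may carry.
#: Platforms with an atypical probe count (below 5,000 or above 60,000)
#: are rejected at load time.
MIN_PLATFORM_FEATURES = 5_000
MAX_PLATFORM_FEATURES = 60_000


class PlatformSizeError(ValueError):
    """Raised when a platform's feature count falls outside the allowed range."""


@dataclass(frozen=True)
class GeneLocus:
    """A mapped locus (gene or EST cluster) with 1-based inclusive coordinates."""

    symbol: str
    chromosome: str
    start: int
    end: int
    biotype: str = KNOWN_GENE

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.symbol}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"{self.symbol}: start ({self.start}) > end ({self.end})"
            )
        if self.biotype not in (KNOWN_GENE, EST_CLUSTER):
            raise ValueError(f"{self.symbol}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeAnnotation:
    """A set of uniquely named loci plus per-chromosome lengths.

    Stands in for the genome-wide gene table a transcriptome mapper ships
    with; here it is an explicit input (TSV) or generated synthetically.
    """

    def __init__(
        self,
        loci: Iterable[GeneLocus],
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.loci: dict[str, GeneLocus] = {}
        for locus in loci:
            if locus.symbol in self.loci:
                raise ValueError(f"duplicate locus symbol {locus.symbol!r}")
            self.loci[locus.symbol] = locus
        if chromosome_lengths is None:
            chromosome_lengths = {}
            for locus in self.loci.values():
                prev = chromosome_lengths.get(locus.chromosome, 0)
                chromosome_lengths[locus.chromosome] = max(prev, locus.end)
        self.chromosome_lengths: dict[str, int] = dict(chromosome_lengths)
        for locus in self.loci.values():
            length = self.chromosome_lengths.get(locus.chromosome)
            if length is None:
                raise ValueError(
                    f"{locus.symbol}: chromosome {locus.chromosome!r} has no length"
                )
            if locus.end > length:
                raise ValueError(
                    f"{locus.symbol}: end {locus.end} beyond chromosome "
                    f"{locus.chromosome} length {length}"
                )

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.loci

    def __getitem__(self, symbol: str) -> GeneLocus:
        return self.loci[symbol]

    def to_frame(self) -> pd.DataFrame:
        """Locus table sorted by (chromosome, start), one row per locus."""
        rows = [
            (l.symbol, l.chromosome, l.start, l.end, l.biotype)
            for l in self.loci.values()
        ]
        df = pd.DataFrame(
            rows, columns=["symbol", "chromosome", "start", "end", "biotype"]
        )
        return df.sort_values(["chromosome", "start", "symbol"]).reset_index(drop=True)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> "GenomeAnnotation":
        loci = [
            GeneLocus(
                symbol=str(r.symbol),
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                biotype=str(getattr(r, "biotype", KNOWN_GENE)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(loci, chromosome_lengths)


@dataclass
class Platform:
    """An array platform: its probe universe and probe-to-symbol map.

    ``probes`` is the full set of features on the array (its size is the
    declared feature count); ``probe_map`` covers only probes that resolve
    to a locus symbol — probes mapping to nothing are legal and are dropped
    (with a logged count) during probe resolution.
    """

    platform_id: str
    probe_map: dict[str, str]
    probes: set[str] = field(default_factory=set)
    enforce_size: bool = True

    def __post_init__(self) -> None:
        if not self.probes:
            self.probes = set(self.probe_map)
        missing = set(self.probe_map) - self.probes
        if missing:
            raise ValueError(
                f"platform {self.platform_id}: {len(missing)} mapped probes "
                "absent from the probe universe"
            )
        if self.enforce_size and not (
            MIN_PLATFORM_FEATURES <= self.feature_count <= MAX_PLATFORM_FEATURES
        ):
            raise PlatformSizeError(
                f"platform {self.platform_id} has {self.feature_count} features; "
                f"accepted range is [{MIN_PLATFORM_FEATURES}, {MAX_PLATFORM_FEATURES}]"
            )

    @property
    def feature_count(self) -> int:
        return len(self.probes)

    @property
    def n_unmapped_probes(self) -> int:
        return self.feature_count - len(self.probe_map)
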