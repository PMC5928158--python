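"""Sliding-window segment maps: tagging, hypergeometric testing, FDR, dedup.

The genome is tiled with fixed windows (default 500 kb, shifted by 250 kb,
so each locus falls in two windows away from chromosome ends).  A window's
value is the mean of its member loci's values; membership is decided by
the gene *start* coordinate so every locus is counted the same number of
times regardless of its length.

A window is *tagged* as a candidate when it contains at least
``min_extreme_genes`` loci flagged in the extreme tails (default: the top
and bottom 2.5th percentile of per-locus values) and its own value is
itself in the corresponding extreme tail of all window values.  Candidates
are then tested: the hypergeometric upper tail gives the probability that
k of the window's n loci are flagged by chance given K flagged among N
genome-wide, and Benjamini-Hochberg correction over all populated windows
(per direction) yields q-values; a candidate is called at q < 0.05.

For differential maps the per-locus value should be the log2 A/B ratio
(symmetric tails); for single-pool maps, the consensus mean.

Single-gene mode reruns the same machinery with a 25 kb window (below half
the ~67 kb mean human protein-coding gene length) and a minimum of one
flagged gene, so a significant window almost always pinpoints one gene;
when a window holds several loci the call is attributed to the flagged
gene only if its absolute value strictly prevails over the other members.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation


@dataclass
class MapConfig:
    """Tunable parameters of the segment map (defaults = standard analysis)."""

    window_size: int = 500_000
    shift: int = 250_000
    extreme_percentile: float = 2.5
    min_extreme_genes: int = 3
    q_threshold: float = 0.05
    single_gene_window: int = 25_000
    single_gene_min: int = 1
    min_samples_per_locus: int = 3

    def __post_init__(self) -> None:
        if self.shift > self.window_size:
            raise ValueError("shift must be <= window_size")
        if not 0 < self.extreme_percentile < 50:
            raise ValueError("extreme_percentile must be in (0, 50)")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")

    @property
    def single_gene_shift(self) -> int:
        return self.single_gene_window // 2


@dataclass(frozen=True)
class FlagSet:
    """Loci in the extreme tails of the per-locus value distribution."""

    over_set: frozenset[str]
    under_set: frozenset[str]
    n_total: int

    @property
    def k_over(self) -> int:
        return len(self.over_set)

    @property
    def k_under(self) -> int:
        return len(self.under_set)


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def build_segments(
    annotation: GenomeAnnotation,
    symbols: Iterable[str],
    window_size: int = 500_000,
    shift: int = 250_000,
) -> pd.DataFrame:
    """Tile every chromosome with windows and record member loci.

    Windows start at 1, 1+shift, 1+2*shift, ... while the start is within
    the chromosome; the last window is clipped at the chromosome end.  A
    locus belongs to a window iff its start coordinate lies inside it.
    Empty windows are retained (they are never callable but keep the
    segment count interpretable).
    """
    wanted = set(symbols)
    ann = annotation.to_frame()
    ann = ann[ann["symbol"].isin(wanted)]
    rows: list[tuple] = []
    for chrom in sorted(annotation.chromosome_lengths, key=_chrom_sort_key):
        length = annotation.chromosome_lengths[chrom]
        sub = ann[ann["chromosome"] == chrom].sort_values("start")
        gene_starts = sub["start"].to_numpy()
        gene_syms = sub["symbol"].to_numpy()
        for ws in range(1, length + 1, shift):
            we = min(ws + window_size - 1, length)
            lo = int(np.searchsorted(gene_starts, ws, side="left"))
            hi = int(np.searchsorted(gene_starts, we, side="right"))
            rows.append((chrom, ws, we, hi - lo, tuple(gene_syms[lo:hi])))
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "n_genes", "loci"]
    )


def _upper_tail_flags(values: np.ndarray, extreme_percentile: float) -> np.ndarray:
    """Boolean mask of the top ``extreme_percentile``% of values.

    The threshold is the linear-interpolation percentile, inclusive.  A tie
    group sitting exactly on the threshold is kept only if it lies entirely
    above the cutoff rank; a group straddling the cutoff is excluded
    wholesale (so a constant map flags nothing).
    """
    n = len(values)
    thr = np.percentile(values, 100.0 - extreme_percentile)
    above = values > thr
    at = values == thr
    if at.any():
        cutoff_rank = n * (1.0 - extreme_percentile / 100.0)
        first_rank_of_group = int((values < thr).sum()) + 1
        if first_rank_of_group > cutoff_rank:
            above = above | at
    return above


def flag_extreme_loci(
    values: pd.Series, extreme_percentile: float = 2.5
) -> FlagSet:
    """Flag loci in the highest and lowest ``extreme_percentile``% tails."""
    v = values.to_numpy(dtype=float)
    symbols = values.index.to_numpy()
    over = _upper_tail_flags(v, extreme_percentile)
    under = _upper_tail_flags(-v, extreme_percentile)
    return FlagSet(
        over_set=frozenset(symbols[over]),
        under_set=frozenset(symbols[under]),
        n_total=len(v),
    )


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that at least k of a window's n loci are flagged by
    chance, given K flagged loci among N genome-wide.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid population: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"invalid draw count k={k} for n={n}, K={K}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    if len(pvalues) == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def tag_and_test_segments(
    segments: pd.DataFrame,
    flags: FlagSet,
    values: pd.Series,
    config: MapConfig,
    min_extreme_genes: int | None = None,
    fdr_scope: str = "populated",
) -> pd.DataFrame:
    """Tag candidate windows, test them, FDR-correct, and call.

    Tagging is descriptive (>= ``min_extreme_genes`` flagged members and a
    window value in the extreme tail of all populated windows); testing is
    the hypergeometric upper tail; correction is Benjamini-Hochberg per
    direction.  With ``fdr_scope="populated"`` (map mode) the correction
    runs over every window containing at least one locus, accounting for
    the full number of windows scanned — this is what keeps null maps
    quiet.  With ``fdr_scope="candidates"`` (single-gene mode, where a
    1-locus window's p is bounded below by K/N and could never survive a
    genome-wide correction) it runs over the tagged candidates only.
    """
    if fdr_scope not in ("populated", "candidates"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    if min_extreme_genes is None:
        min_extreme_genes = config.min_extreme_genes
    seg = segments.copy()
    vmap = values.to_dict()
    seg_values = np.full(len(seg), np.nan)
    k_over = np.zeros(len(seg), dtype=int)
    k_under = np.zeros(len(seg), dtype=int)
    over_set, under_set = flags.over_set, flags.under_set
    loci_col = seg["loci"].to_numpy()
    for i, loci in enumerate(loci_col):
        if not loci:
            continue
        seg_values[i] = float(np.mean([vmap[s] for s in loci]))
        k_over[i] = sum(1 for s in loci if s in over_set)
        k_under[i] = sum(1 for s in loci if s in under_set)
    seg["segment_value"] = seg_values
    seg["k_over"] = k_over
    seg["k_under"] = k_under

    populated = seg["n_genes"].to_numpy() >= 1
    pop_vals = seg_values[populated]
    alpha = config.extreme_percentile
    if pop_vals.size:
        thr_hi = np.percentile(pop_vals, 100.0 - alpha)
        thr_lo = np.percentile(pop_vals, alpha)
    else:
        thr_hi = thr_lo = np.nan

    cand_over = populated & (k_over >= min_extreme_genes) & (seg_values >= thr_hi)
    cand_under = populated & (k_under >= min_extreme_genes) & (seg_values <= thr_lo)

    n_genes = seg["n_genes"].to_numpy()
    N, K_over, K_under = flags.n_total, flags.k_over, flags.k_under
    p_over = np.ones(len(seg))
    p_under = np.ones(len(seg))
    idx = np.flatnonzero(populated)
    p_over[idx] = hypergeom.sf(k_over[idx] - 1, N, K_over, n_genes[idx])
    p_under[idx] = hypergeom.sf(k_under[idx] - 1, N, K_under, n_genes[idx])
    np.clip(p_over, 0.0, 1.0, out=p_over)
    np.clip(p_under, 0.0, 1.0, out=p_under)
    q_over = np.full(len(seg), np.nan)
    q_under = np.full(len(seg), np.nan)
    if fdr_scope == "populated":
        q_over[idx] = _bh_qvalues(p_over[idx])
        q_under[idx] = _bh_qvalues(p_under[idx])
    else:
        over_idx = np.flatnonzero(cand_over)
        under_idx = np.flatnonzero(cand_under)
        q_over[over_idx] = _bh_qvalues(p_over[over_idx])
        q_under[under_idx] = _bh_qvalues(p_under[under_idx])

    seg["candidate_over"] = cand_over
    seg["candidate_under"] = cand_under
    seg["p_over"] = p_over
    seg["p_under"] = p_under
    seg["q_over"] = q_over
    seg["q_under"] = q_under

    with np.errstate(invalid="ignore"):
        called_over = cand_over & (q_over < config.q_threshold)
        called_under = cand_under & (q_under < config.q_threshold)
    call = np.where(called_over, "over", np.where(called_under, "under", "none"))
    both = called_over & called_under
    if both.any():  # pathological; resolve by the smaller q
        call[both & (q_under < q_over)] = "under"
        call[both & (q_over <= q_under)] = "over"
    seg["call"] = call
    seg["p"] = np.where(call == "under", p_under, p_over)
    seg["q"] = np.where(call == "under", q_under, q_over)
    return seg


def deduplicate_segments(called: pd.DataFrame) -> pd.DataFrame:
    """Collapse chains of overlapping same-direction calls with similar genes.

    Consecutive called windows (sorted by chromosome, start) are chained
    when they share more than half of the union of their gene sets
    (Jaccard > 0.5); each chain keeps its most extreme window (largest
    value for over-calls, smallest for under-calls; ties broken by smaller
    q, then leftmost start).
    """
    keep_rows = []
    for direction in ("over", "under"):
        sub = called[called["call"] == direction]
        if len(sub) == 0:
            continue
        sub = sub.sort_values(
            ["chromosome", "start"],
            key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
        )
        chain: list[pd.Series] = []
        prev = None
        for _, row in sub.iterrows():
            if prev is not None and row["chromosome"] == prev["chromosome"]:
                a, b = set(prev["loci"]), set(row["loci"])
                union = a | b
                jaccard = len(a & b) / len(union) if union else 0.0
                linked = jaccard >= 0.5  # "similar gene content"
            else:
                linked = False
            if linked:
                chain.append(row)
            else:
                if chain:
                    keep_rows.append(_best_of_chain(chain, direction))
                chain = [row]
            prev = row
        if chain:
            keep_rows.append(_best_of_chain(chain, direction))
    if not keep_rows:
        return called.iloc[0:0].copy()
    out = pd.DataFrame(keep_rows)
    return out.sort_values(
        ["chromosome", "start"],
        key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
    ).reset_index(drop=True)


def _best_of_chain(chain: list[pd.Series], direction: str) -> pd.Series:
    sign = -1.0 if direction == "over" else 1.0

    def key(row: pd.Series):
        return (sign * row["segment_value"], row["q"], row["start"])

    return min(chain, key=key)


def single_gene_mode(
    values: pd.Series,
    annotation: GenomeAnnotation,
    config: MapConfig,
) -> pd.DataFrame:
    """Gene-level significance via narrow windows (25 kb, min 1 flagged gene).

    Returns one row per attributed gene with its direction and the best
    (smallest) q among the windows that pinpoint it.  In a multi-gene
    window the call is attributed only when the flagged gene's |value|
    strictly prevails over every other member's.
    """
    flags = flag_extreme_loci(values, config.extreme_percentile)
    segs = build_segments(
        annotation, values.index, config.single_gene_window, config.single_gene_shift
    )
    scored = tag_and_test_segments(
        segs, flags, values, config,
        min_extreme_genes=config.single_gene_min, fdr_scope="candidates",
    )
    called = scored[scored["call"] != "none"]
    best: dict[str, dict] = {}
    vmap = values.to_dict()
    for _, row in called.iterrows():
        direction = row["call"]
        flagged = flags.over_set if direction == "over" else flags.under_set
        members = row["loci"]
        hits = [s for s in members if s in flagged]
        for sym in hits:
            if len(members) > 1:
                mag = abs(vmap[sym])
                if any(abs(vmap[m]) >= mag for m in members if m != sym):
                    continue  # does not prevail over the other members
            locus = annotation[sym]
            prev = best.get(sym)
            if prev is None or row["q"] < prev["q"]:
                best[sym] = {
                    "symbol": sym,
                    "chromosome": locus.chromosome,
                    "start": locus.start,
                    "end": locus.end,
                    "value": vmap[sym],
                    "direction": direction,
                    "p": row["p"],
                    "q": row["q"],
                    "window_start": row["start"],
                    "window_end": row["end"],
                }
    cols = ["symbol", "chromosome", "start", "end", "value", "direction",
            "p", "q", "window_start", "window_end"]
    if not best:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(list(best.values()), columns=cols)
    return out.sort_values(
        ["chromosome", "start"],
        key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
    ).reset_index(drop=True)


def chromosome_mean_ratio(
    comparison: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Per-chromosome A/B ratio of mean expression, with ranks.

    The ratio is (mean of pool-A means over the chromosome's loci) /
    (mean of pool-B means), i.e. the chromosome-level dosage signal; rank 1
    is the most over-expressed chromosome.  Chromosomes without loci in
    the comparison are omitted.
    """
    if len(comparison) == 0:
        raise ValueError("empty comparison map")
    chrom = pd.Series(
        {s: annotation[s].chromosome for s in comparison.index}, name="chromosome"
    )
    df = comparison[["meanA", "meanB"]].join(chrom)
    grouped = df.groupby("chromosome")
    out = pd.DataFrame(
        {
            "n_loci": grouped.size(),
            "meanA": grouped["meanA"].mean(),
            "meanB": grouped["meanB"].mean(),
        }
    )
    out["ratio"] = out["meanA"] / out["meanB"]
    out["rank"] = out["ratio"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank")
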