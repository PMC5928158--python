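import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from trisomap.annotation import GeneLocus, GenomeAnnotation
from trisomap.segments import (
    MapConfig,
    build_segments,
    chromosome_mean_ratio,
    deduplicate_segments,
    flag_extreme_loci,
    hypergeometric_pvalue,
    single_gene_mode,
    tag_and_test_segments,
)


def grid_annotation(n_genes, spacing=60_000, chrom="1", start0=10_000,
                    length=None):
    """Evenly spaced 1 kb loci on one chromosome."""
    loci = [
        GeneLocus(f"g{chrom}_{i}", chrom, start0 + i * spacing,
                  start0 + i * spacing + 999)
        for i in range(n_genes)
    ]
    if length is None:
        length = start0 + n_genes * spacing + 10_000
    return GenomeAnnotation(loci, {chrom: length})


class TestBuildSegments:
    def test_default_tiling_on_1mb_chromosome(self):
        ann = grid_annotation(3, chrom="1", length=1_000_000)
        seg = build_segments(ann, [l for l in ann.loci], 500_000, 250_000)
        assert seg["start"].tolist() == [1, 250_001, 500_001, 750_001]
        assert seg["end"].tolist() == [500_000, 750_000, 1_000_000, 1_000_000]

    def test_membership_by_gene_start(self):
        loci = [GeneLocus("g", "1", 300_000, 400_000)]
        ann = GenomeAnnotation(loci, {"1": 1_000_000})
        seg = build_segments(ann, ["g"], 500_000, 250_000)
        member = seg[seg["loci"].map(lambda t: "g" in t)]
        assert member["start"].tolist() == [1, 250_001]

    def test_empty_chromosome_retains_empty_segments(self):
        ann = GenomeAnnotation(
            [GeneLocus("g", "1", 10, 20)], {"1": 600_000, "2": 600_000}
        )
        seg = build_segments(ann, ["g"], 500_000, 250_000)
        chr2 = seg[seg["chromosome"] == "2"]
        assert len(chr2) == 3
        assert (chr2["n_genes"] == 0).all()

    def test_each_locus_in_two_windows_away_from_ends(self):
        ann = grid_annotation(100, spacing=50_000, length=6_000_000)
        seg = build_segments(ann, list(ann.loci), 500_000, 250_000)
        counts = {}
        for loci in seg["loci"]:
            for s in loci:
                counts[s] = counts.get(s, 0) + 1
        interior = [
            s for s, l in ann.loci.items()
            if l.start > 500_000 and l.start <= 6_000_000 - 500_000
        ]
        assert all(counts[s] == 2 for s in interior)


class TestFlagExtremeLoci:
    def test_integer_grid_tails(self):
        values = pd.Series(
            np.arange(1, 1001, dtype=float), index=[f"g{i}" for i in range(1000)]
        )
        flags = flag_extreme_loci(values, 2.5)
        assert flags.k_over == 25
        assert flags.over_set == frozenset(f"g{i}" for i in range(975, 1000))
        assert flags.k_under == 25
        assert flags.under_set == frozenset(f"g{i}" for i in range(25))

    def test_forty_loci_give_one_per_tail(self):
        values = pd.Series(
            np.arange(40, dtype=float), index=[f"g{i}" for i in range(40)]
        )
        flags = flag_extreme_loci(values, 2.5)
        assert flags.over_set == frozenset({"g39"})
        assert flags.under_set == frozenset({"g0"})

    def test_constant_map_flags_nothing(self):
        values = pd.Series(np.ones(100), index=[f"g{i}" for i in range(100)])
        flags = flag_extreme_loci(values, 2.5)
        assert flags.k_over == 0 and flags.k_under == 0


class TestHypergeometricPvalue:
    def test_zero_successes_is_certain(self):
        assert hypergeometric_pvalue(0, 5, 10, 100) == 1.0

    def test_drawing_everything_is_certain(self):
        assert hypergeometric_pvalue(5, 10, 5, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # literal enumeration over all C(20, 6) draws from a 20-item
        # population with 5 marked items
        N, K, n = 20, 5, 6
        population = [1] * K + [0] * (N - K)
        draws = list(itertools.combinations(range(N), n))
        for k in range(0, min(n, K) + 1):
            count = sum(
                1 for d in draws if sum(population[i] for i in d) >= k
            )
            expected = count / len(draws)
            assert hypergeometric_pvalue(k, n, K, N) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("k,n,K,N", [(-1, 5, 5, 10), (6, 5, 5, 10),
                                         (3, 11, 5, 10), (3, 5, 11, 10)])
    def test_invalid_parameters_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(k, n, K, N)


def scored_toy_map(n_background=2000, planted_value=math.log2(3.0),
                   n_planted=8, seed=0, config=None):
    """Background loci at log-ratio ~0 plus one window of planted loci."""
    if config is None:
        config = MapConfig()
    rng = np.random.default_rng(seed)
    loci = []
    values = {}
    spacing = 80_000
    n_per_chrom = 250
    chrom_len = n_per_chrom * spacing + 20_000
    lengths = {}
    i = 0
    for c in range(n_background // n_per_chrom):
        chrom = str(c + 1)
        lengths[chrom] = chrom_len
        for j in range(n_per_chrom):
            sym = f"g{i}"
            start = 10_000 + j * spacing
            loci.append(GeneLocus(sym, chrom, start, start + 999))
            values[sym] = rng.normal(0.0, 0.05)
            i += 1
    # planted window: n_planted loci packed into 500 kb on their own chromosome
    lengths["P"] = 2_000_000
    for j in range(n_planted):
        sym = f"planted{j}"
        start = 500_001 + j * (499_000 // max(n_planted - 1, 1))
        loci.append(GeneLocus(sym, "P", start, start + 999))
        values[sym] = planted_value
    ann = GenomeAnnotation(loci, lengths)
    values = pd.Series(values)
    from trisomap.segments import flag_extreme_loci as flag

    flags = flag(values, config.extreme_percentile)
    seg = build_segments(ann, values.index, config.window_size, config.shift)
    scored = tag_and_test_segments(seg, flags, values, config)
    return ann, values, flags, scored


class TestTagAndTest:
    def test_planted_window_is_called_over(self):
        _, _, _, scored = scored_toy_map()
        planted_rows = scored[
            scored["loci"].map(lambda t: any(s.startswith("planted") for s in t))
        ]
        assert (planted_rows["call"] == "over").any()

    def test_too_few_flagged_genes_blocks_candidacy(self):
        _, _, _, scored = scored_toy_map(n_planted=2)
        planted_rows = scored[
            scored["loci"].map(lambda t: any(s.startswith("planted") for s in t))
        ]
        assert not planted_rows["candidate_over"].any()
        assert (planted_rows["call"] == "none").all()

    def test_extreme_genes_with_mid_segment_value_not_candidate(self):
        # three flagged loci diluted by many strongly negative members pull
        # the window value to the middle: no candidacy despite k >= 3
        config = MapConfig()
        rng = np.random.default_rng(1)
        loci, values, lengths = [], {}, {}
        spacing = 80_000
        lengths["1"] = 250 * spacing + 20_000
        for j in range(250):
            sym = f"bg{j}"
            start = 10_000 + j * spacing
            loci.append(GeneLocus(sym, "1", start, start + 999))
            values[sym] = rng.normal(0.0, 0.05)
        lengths["P"] = 1_000_000
        for j, v in enumerate([3.0, 3.0, 3.0] + [-3.0] * 9):
            sym = f"mix{j}"
            start = 100_001 + j * 30_000
            loci.append(GeneLocus(sym, "P", start, start + 999))
            values[sym] = v
        ann = GenomeAnnotation(loci, lengths)
        values = pd.Series(values)
        flags = flag_extreme_loci(values, config.extreme_percentile)
        assert sum(1 for s in flags.over_set if s.startswith("mix")) == 3
        seg = build_segments(ann, values.index, config.window_size, config.shift)
        scored = tag_and_test_segments(seg, flags, values, config)
        mix_rows = scored[
            scored["loci"].map(lambda t: sum(s.startswith("mix") for s in t) >= 3)
        ]
        assert (mix_rows["k_over"] >= 3).any()
        assert not mix_rows["candidate_over"].any()

    def test_q_never_below_p(self):
        _, _, _, scored = scored_toy_map()
        pop = scored[scored["n_genes"] >= 1]
        assert (pop["q_over"] >= pop["p_over"] - 1e-12).all()
        assert (pop["q_under"] >= pop["p_under"] - 1e-12).all()

    def test_all_p_one_yields_no_calls(self):
        # constant map: no flags, every p = 1, nothing called
        values = pd.Series(np.ones(300), index=[f"g{i}" for i in range(300)])
        ann = grid_annotation(300, spacing=60_000)
        flags = flag_extreme_loci(values, 2.5)
        seg = build_segments(ann, values.index, 500_000, 250_000)
        scored = tag_and_test_segments(seg, flags, values, MapConfig())
        assert (scored["call"] == "none").all()
        pop = scored[scored["n_genes"] >= 1]
        assert (pop["p_over"] == 1.0).all()

    def test_called_segments_satisfy_tag_conditions_post_hoc(self):
        _, values, flags, scored = scored_toy_map()
        called = scored[scored["call"] == "over"]
        assert len(called) > 0
        pop = scored[scored["n_genes"] >= 1]
        thr = np.percentile(pop["segment_value"], 97.5)
        assert (called["k_over"] >= 3).all()
        assert (called["segment_value"] >= thr).all()


def _seg_row(chrom, start, end, loci, value, q, call="over"):
    return {
        "chromosome": chrom, "start": start, "end": end, "loci": tuple(loci),
        "n_genes": len(loci), "segment_value": value, "q": q, "call": call,
    }


class TestDeduplicate:
    def test_overlapping_chain_keeps_most_extreme(self):
        called = pd.DataFrame([
            _seg_row("1", 1, 500_000, ["a", "b", "c"], 2.8, 0.01),
            _seg_row("1", 250_001, 750_000, ["b", "c", "d"], 3.1, 0.02),
        ])
        out = deduplicate_segments(called)
        assert len(out) == 1
        assert out.iloc[0]["segment_value"] == 3.1

    def test_different_chromosomes_both_kept(self):
        called = pd.DataFrame([
            _seg_row("1", 1, 500_000, ["a", "b", "c"], 2.8, 0.01),
            _seg_row("2", 1, 500_000, ["x", "y", "z"], 3.1, 0.02),
        ])
        assert len(deduplicate_segments(called)) == 2

    def test_identical_content_equal_values_keeps_leftmost(self):
        called = pd.DataFrame([
            _seg_row("1", 250_001, 750_000, ["a", "b", "c"], 2.8, 0.01),
            _seg_row("1", 1, 500_000, ["a", "b", "c"], 2.8, 0.01),
        ])
        out = deduplicate_segments(called)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 1

    def test_under_direction_keeps_smallest_value(self):
        called = pd.DataFrame([
            _seg_row("1", 1, 500_000, ["a", "b", "c"], -2.8, 0.01, "under"),
            _seg_row("1", 250_001, 750_000, ["b", "c", "d"], -3.1, 0.02, "under"),
        ])
        out = deduplicate_segments(called)
        assert out.iloc[0]["segment_value"] == -3.1

    def test_low_overlap_calls_not_chained(self):
        called = pd.DataFrame([
            _seg_row("1", 1, 500_000, ["a", "b", "c", "d"], 2.8, 0.01),
            _seg_row("1", 250_001, 750_000, ["d", "e", "f", "g"], 3.1, 0.02),
        ])
        assert len(deduplicate_segments(called)) == 2  # jaccard 1/7 < 0.5


class TestSingleGeneMode:
    def _background(self, rng, n=500):
        loci, values, lengths = [], {}, {"1": 500 * 80_000 + 20_000}
        for j in range(n):
            sym = f"bg{j}"
            start = 10_000 + j * 80_000
            loci.append(GeneLocus(sym, "1", start, start + 999))
            values[sym] = rng.normal(0.0, 0.05)
        return loci, values, lengths

    def test_isolated_flagged_gene_is_called(self):
        rng = np.random.default_rng(0)
        loci, values, lengths = self._background(rng)
        lengths["P"] = 1_000_000
        loci.append(GeneLocus("hot", "P", 500_000, 501_000))
        values["hot"] = 3.0
        ann = GenomeAnnotation(loci, lengths)
        out = single_gene_mode(pd.Series(values), ann, MapConfig())
        assert "hot" in set(out["symbol"])
        row = out[out["symbol"] == "hot"].iloc[0]
        assert row["direction"] == "over"
        assert row["q"] < 0.05

    def test_flagged_gene_prevailing_over_neighbor_attributed(self):
        rng = np.random.default_rng(0)
        loci, values, lengths = self._background(rng)
        lengths["P"] = 1_000_000
        loci.append(GeneLocus("hot", "P", 500_000, 501_000))
        values["hot"] = 3.0
        loci.append(GeneLocus("neighbor", "P", 510_000, 511_000))
        values["neighbor"] = 0.0
        ann = GenomeAnnotation(loci, lengths)
        out = single_gene_mode(pd.Series(values), ann, MapConfig())
        assert "hot" in set(out["symbol"])
        assert "neighbor" not in set(out["symbol"])

    def test_non_prevailing_flagged_gene_not_attributed(self):
        rng = np.random.default_rng(0)
        loci, values, lengths = self._background(rng)
        lengths["P"] = 1_000_000
        # two flagged genes share every window; neither strictly prevails
        loci.append(GeneLocus("hotA", "P", 500_001, 500_050))
        loci.append(GeneLocus("hotB", "P", 500_100, 500_150))
        values["hotA"] = 3.0
        values["hotB"] = 3.0
        ann = GenomeAnnotation(loci, lengths)
        out = single_gene_mode(pd.Series(values), ann, MapConfig())
        assert "hotA" not in set(out["symbol"])
        assert "hotB" not in set(out["symbol"])


class TestChromosomeMeanRatio:
    def _comparison(self, rows):
        df = pd.DataFrame(rows).set_index("symbol")
        return df

    def test_two_chromosome_toy(self):
        ann = GenomeAnnotation(
            [GeneLocus("a", "1", 1, 10), GeneLocus("b", "2", 1, 10)],
            {"1": 100, "2": 100},
        )
        comp = self._comparison([
            {"symbol": "a", "meanA": 150.0, "meanB": 100.0},
            {"symbol": "b", "meanA": 100.0, "meanB": 100.0},
        ])
        out = chromosome_mean_ratio(comp, ann)
        assert out.loc["1", "ratio"] == pytest.approx(1.5)
        assert out.loc["2", "ratio"] == pytest.approx(1.0)
        assert out.loc["1", "rank"] == 1

    def test_uniform_ratios_give_unit_chromosome_ratios(self):
        ann = grid_annotation(10, spacing=1_000)
        comp = self._comparison([
            {"symbol": s, "meanA": 42.0, "meanB": 42.0} for s in ann.loci
        ])
        out = chromosome_mean_ratio(comp, ann)
        assert np.allclose(out["ratio"], 1.0)

    def test_empty_comparison_is_an_error(self):
        ann = grid_annotation(2, spacing=1_000)
        with pytest.raises(ValueError):
            chromosome_mean_ratio(
                pd.DataFrame(columns=["meanA", "meanB"]), ann
            )
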