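# Methods

## Model and assumptions

The package treats bulk expression measurements as positive intensities
whose within-condition variation is multiplicative.  For locus *g*, pool
mean `μ_B(g)` in the euploid condition and `μ_A(g) = r_g · μ_B(g)` in the
trisomic condition, where `r_g` is the true dosage ratio (1.5 for a fully
dosage-sensitive gene on the trisomic chromosome, 1 for an escaping or
unaffected gene, 2/3 for trans-inhibited genes).  Samples measure
`μ · ε` with lognormal noise `ε`, through platform-specific probe
affinities and a smooth monotone intensity distortion.  The pipeline's
claim is that two normalization stages plus record-level averaging recover
`r_g` well enough to rank chromosomes, classify dosage bands and detect
regional runs of extreme loci.

Key assumptions: noise is multiplicative and positive; platform
distortions are monotone in intensity (what quantile-based normalization
can remove); probes of one locus are exchangeable up to a fixed affinity;
samples within a pool are biologically exchangeable.

## Normalization

*Thresholding.*  Values ≤ 0 become `0.95 × min positive value` of their
sample, before any normalization.  Zeros cannot enter ratios; treating
them as "below detection" preserves strong over-expression instead of
discarding it.  The factor 0.95 is configurable (`threshold_factor`).

*Global normalization.*  `v → 100·v / mean(v)` per sample; output mean is
exactly 100 (percent-of-mean units).  Thresholding precedes this step, so
the mean is taken over thresholded values; the ordering is a design choice
documented here because only the threshold rule itself, not its position,
is externally fixed.

*Scaled quantile normalization.*  Grid size `n_points = 1001` (default):
for each sample, `numpy.quantile` (linear interpolation) at probabilities
`k/(n_points−1)`; reference = pointwise mean across **all** samples of
both pools jointly; each value maps to the reference at its fractional
within-sample rank (mean rank for ties, linear interpolation on the grid).
Building the reference per pool instead would erase the pool-level shifts
the differential map is meant to measure.  At equal feature counts with
`n_points` equal to that count the procedure reduces exactly to classical
quantile normalization — this is enforced by an oracle test.  1001 points
resolve the quantile curve to 0.1% while remaining far below the smallest
admissible platform (5,000 features).

## Integration and dosage bands

The consensus is the arithmetic mean over all (probe, sample) records of a
locus, not a mean of per-sample means: a locus measured by three probes on
one array contributes three records.  Records and distinct samples are
counted separately; loci with fewer than `min_samples_per_locus = 3`
biological samples in a pool are excluded from that pool's map.
Percentiles are mean-rank percentiles among retained loci (a single
retained locus sits at percentile 100).

Bands: over `≥ 1.30`, under `≤ 0.76`, neutral `0.77–1.29`, evaluated on
the ratio rounded half-up to 2 decimals (the band boundaries are 2-decimal
numbers; half-up rather than banker's rounding so 1.295 classifies as
1.30).  The dosage model constants (3:2 = 1.5, 2:3 ≈ 0.67) are exposed but
only the band edges enter classification.

## Segment maps

Windows of `window_size = 500 kb` start at 1, 1+shift, … (`shift =
250 kb`), clipped at the chromosome end; a locus belongs to a window iff
its **start** coordinate falls inside, so every locus is counted twice
(away from chromosome ends) regardless of gene length.  For differential
maps the per-locus value is the log₂ ratio — symmetric tails, so
over- and under-expression are flagged on the same footing; for
single-pool maps it is the consensus mean.

Extreme flags: inclusive thresholds at the linear-interpolation
percentiles (`extreme_percentile = 2.5`); a tie group exactly on the
threshold is kept only when it lies entirely inside the tail, so a
constant map flags nothing.

Candidate windows need `k ≥ min_extreme_genes = 3` flagged members *and*
a window value in the corresponding extreme tail of all populated-window
values.  Testing is the hypergeometric upper tail `P(X ≥ k)` with
`X ~ Hypergeom(N, K, n)` (N retained loci, K flagged, n window members).
FDR: Benjamini–Hochberg per direction **over all windows containing at
least one locus**, with calls at `q < 0.05` restricted to candidates.
Correcting only over candidates would be strongly anti-conservative — the
co-location that creates a candidate also creates its small p-value, and
simulated null maps would produce calls in most runs; with the
all-populated-windows family, null maps (5,000 i.i.d. loci) contain a
call in only ~2% of runs.  Deduplication chains consecutive
same-direction calls sharing at least half of their gene-set union
(Jaccard ≥ 0.5) and keeps the most extreme window (ties: smaller q, then
leftmost).

Single-gene mode reruns the machinery at `25 kb / 12.5 kb` with a 1-gene
minimum.  Here the FDR family is the candidate set: a 1-gene window's p
is bounded below by `K/N ≈ 0.025`, so a genome-wide correction over ~32,000
narrow windows could never call anything; within the candidate family the
q-value equals the flagged fraction, which is the intended gene-level
significance.  When a narrow window holds several loci, the call is
attributed to a flagged gene only if its |log₂ ratio| is strictly the
largest among members ("prevails").

Chromosome summary: per chromosome, `mean(meanA) / mean(meanB)` over its
loci, ranked descending — the chromosome-level dosage signal.

## Synthetic data: what it emulates, what it does not

The generator reproduces: multi-platform pools (default three platforms,
coverage 0.95/0.85/0.70 of the genome, 1–3 probes per locus, ~2% unmapped
control probes), per-probe lognormal affinities (σ = 0.1), monotone
power-law intensity bias per platform (`v → m·(v/m)^(1+β)`, β ∈
[−0.08, 0.10]), per-sample lognormal noise (σ = 0.2), mixed
linear/ln/log₂ emission, a trisomic chromosome (labelled "21") at dosage
1.5 with an escape fraction (default 0.3), trans-affected genes (25 up,
25 down), and optional planted segments.  The default genome is 10
chromosomes × 500 loci on 40 Mb (~6 loci per 500 kb window, matching
typical human transcript density at genome scale), baseline expression
lognormal with between-gene σ = 1, ~15% of loci labelled EST clusters.
Samples are assigned to platforms round-robin, 10 per pool by default.

Not emulated: probe-level sequence effects, batch/covariate structure,
correlated (chromatin-domain) noise, RNA-seq counts, missing-not-at-random
probes.  Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its robustness to monotone platform distortion and
lognormal noise — not robustness to confounded real-world batch structure.

Problem sizes in the test battery were chosen at desk scale: 100 seeded
end-to-end runs for dosage recovery, 20 planted-segment maps and 200 null
maps for the caller, a ≤ 25-item population sweep for the exact
hypergeometric check.  Each end-to-end run takes well under a second.

## Numerical choices and degenerate inputs

- Ratios are compared at 2 decimals with half-up rounding (see bands).
- The quantile reference is forced nondecreasing
  (`numpy.maximum.accumulate`) to absorb float jitter in the mean curve.
- Hypergeometric p-values are clipped to [0, 1] before BH.
- A sample with no positive values, an empty pool, an empty record list,
  zero shared loci, or zero-variance correlation input all raise
  `ValueError` rather than returning NaNs.
- Expression values absent from an input table are "not measured", never
  zero; duplicate probe ids in one table are an error (ambiguous input).
- Platforms outside 5,000–60,000 features are rejected at load; the bound
  is inclusive on both ends.
- Full determinism: one integer seed fixes annotation, truth, platforms
  and samples; identical seeds yield byte-identical output bundles.

## The expected footprint of global normalization

With 10% of loci at dosage 1.5 and escape 0, the trisomic pool's sample
means are inflated by ~5%, so percent-of-mean normalization compresses the
recovered trisomic ratio to ≈ 1.43–1.48 rather than 1.5.  This is a
property of the method, not an implementation artifact — published
per-tissue dosage ratios of canonical dosage-sensitive genes show the same
mild compression — and the recovery band used in the tests ([1.40, 1.60])
accounts for it.

## Known limitations

- The segment caller controls FDR at 5%, not family-wise error: over many
  maps, occasional calls outside truly affected regions are expected (≈1%
  of calls in the planted-segment benchmark) and are the price of its
  sensitivity.
- EST-cluster annotation is taken at face value from the input gene table;
  no identifier resolution beyond the supplied platform maps is attempted.
- Consensus means weight records, not samples; a locus with many probes on
  one platform is influenced more by that platform.  A per-sample-mean
  alternative would be a one-line change in `pool_loci` and is a
  reasonable configuration switch for future work.
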