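"""Simulate a multi-platform trisomy dataset and build its differential map.

Generates 10 trisomic + 10 euploid samples spread over three array
platforms (different feature counts, intensity biases and emission scales),
runs the full pipeline (linearize -> resolve probes -> threshold -> global
normalization -> scaled quantile normalization -> per-locus consensus ->
A/B ratios), and prints how well the known 3:2 dosage signal is recovered.
"""

from trisomap import (
    SyntheticConfig,
    generate_annotation,
    run_differential_map,
    simulate_pools,
)

config = SyntheticConfig(seed=1, escape_fraction=0.3)
annotation = generate_annotation(config)
samples_a, samples_b, platforms, truth = simulate_pools(config, annotation)

result = run_differential_map(samples_a, samples_b, platforms, annotation)

joined = result.comparison.join(truth.genes[["gene_class"]])
trisomic = joined[joined["gene_class"] == "trisomic"]
escaping = joined[joined["gene_class"] == "escape"]
background = joined[joined["gene_class"] == "background"]

print(f"shared loci in both pools: {len(result.comparison)}")
print(f"median ratio, trisomic non-escaping genes: "
      f"{trisomic['ratio'].median():.3f}   (true dosage 1.5)")
print(f"median ratio, dosage-escaping genes:      "
      f"{escaping['ratio'].median():.3f}   (true ratio 1.0)")
print(f"median ratio, background genes:           "
      f"{background['ratio'].median():.3f}   (true ratio 1.0)")
top = result.chromosome_summary.iloc[0]
print(f"most over-expressed chromosome: {result.chromosome_summary.index[0]} "
      f"(ratio {top['ratio']:.3f}) — the trisomic chromosome should rank #1")
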