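"""Extreme-QTL genome scan on a simulated cross.

Simulates a haploid two-parent cross segregating for two opposing-effect
readthrough loci, sorts the top and bottom 1% of the population on a
noisy reporter signal, synthesizes pooled allele-specific probe
intensities, and scans for allele-frequency skews. Scaled to 4,000
markers and 4,000 segregants so it runs in a few seconds.
"""

from termvar.pipeline import run_xqtl, simulate_cross
from termvar.simulate import CrossConfig, SelectionConfig, default_trait_model

model = default_trait_model()
config = CrossConfig(n_markers=4_000, n_segregants=4_000, seed=1)
population = simulate_cross(config, model, seed=2)
experiment = run_xqtl(population, SelectionConfig(), n_null=50, seed=3)

print(f"{population.n_segregants} segregants, "
      f"{population.marker_map.n_markers} markers, "
      f"pools of {experiment.pool_size} cells per 1% tail")
print(f"familywise null band (50 mock selections): "
      f"|smoothed skew| > {experiment.high.threshold:.3f}")
print()
for name, res in (("high", experiment.high), ("low", experiment.low)):
    print(f"{name}-readthrough pool: {len(res.peaks)} peak(s)")
    for p in res.peaks:
        parent = "BY" if p.sign > 0 else "RM"
        print(f"  chr{p.chrom:02d}:{p.pos:>9,d}  smoothed skew {p.value:+.2f} "
              f"({parent}-allele enriched), interval "
              f"{p.start:,d}-{p.end:,d}")
print()
print("True loci: chr15:560,000 (BY allele raises readthrough) and")
print("chr02:360,000 (RM allele raises readthrough). Each pool recovers both")
print("loci with the expected, mutually opposite, enrichment directions:")
print("positive skew = BY-enriched, negative = RM-enriched.")
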