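"""Dissecting a two-locus architecture by fixing loci and rescanning.

Repeats the genome scan on the same simulated cross after removing each
trait locus's effect (emulating crosses whose parents share that allele):
fixing one locus erases exactly its peak, fixing both erases the signal
entirely.
"""

from termvar.pipeline import run_xqtl, simulate_cross
from termvar.simulate import (CrossConfig, SelectionConfig, assign_trait,
                              default_trait_model)

model = default_trait_model()
config = CrossConfig(n_markers=4_000, n_segregants=4_000, seed=1)
population = simulate_cross(config, model, seed=2)

scenarios = (
    ("full cross (TRM10 + SUP45 segregating)", model),
    ("TRM10 fixed", model.without("TRM10")),
    ("TRM10 and SUP45 fixed", model.without("TRM10").without("SUP45")),
)
for label, m in scenarios:
    scanned = assign_trait(population, m, seed=5)
    exp = run_xqtl(scanned, SelectionConfig(), n_null=50, seed=6)
    peaks = {name: [(f"chr{p.chrom:02d}:{p.pos:,d}", "BY" if p.sign > 0 else "RM")
                    for p in getattr(exp, name).peaks]
             for name in ("high", "low")}
    print(f"{label}:")
    print(f"  high pool peaks: {peaks['high'] or 'none'}")
    print(f"  low pool peaks : {peaks['low'] or 'none'}")
print()
print("Each remaining peak marks a locus still segregating for a readthrough")
print("effect; the no-peak scan shows the null band correctly absorbs pool")
print("drift and array noise when no locus is under selection.")
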