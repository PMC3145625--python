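"""Quantify stop-codon readthrough from dual-luciferase plate readings.

Builds a small synthetic plate for the two parent strains at their
published summary ratios, runs the estimation pipeline (background
subtraction, firefly/Renilla ratios, sense-normalization, replicate
summaries) and prints per-strain percent readthrough.
"""

import numpy as np
import pandas as pd

from termvar.readthrough import estimate_readthrough, readthrough_percent

rng = np.random.default_rng(1)


def plate_rows(strain, sense_ratio, stop_ratio, n=8):
    """Eight assays per construct with 3% multiplicative assay noise."""
    rows = []
    for i in range(n):
        for construct, ratio in (("sense", sense_ratio), ("stop", stop_ratio)):
            renilla = 5000 * (1 + rng.normal(0, 0.03))
            rows.append(dict(
                strain=strain, construct=construct,
                firefly_rlu=ratio * renilla * (1 + rng.normal(0, 0.03)) + 40,
                renilla_rlu=renilla + 30,
                firefly_bg=40.0, renilla_bg=30.0,
                assay_id=f"a{i}", bio_rep=f"b{i % 4}"))
    return rows


plate = pd.DataFrame(plate_rows("BY4724", 0.633, 0.00173)
                     + plate_rows("RM11-1a", 0.780, 0.00381))
estimates = estimate_readthrough(plate)

print("Direct arithmetic on the summary ratios:")
print(f"  BY4724 : {readthrough_percent(0.00173, 0.633):.3f} %")
print(f"  RM11-1a: {readthrough_percent(0.00381, 0.780):.3f} %")
print()
print("Pipeline estimates from the simulated plate (mean +/- SD, n assays):")
for row in estimates.itertuples(index=False):
    print(f"  {row.strain:8s} {row.mean_pct:.3f} +/- {row.sd_pct:.3f} %  (n={row.n_assays})")
print()
print("Readthrough is the firefly/Renilla ratio of the stop-codon reporter")
print("as a percentage of the sense-codon reporter's ratio: the fraction of")
print("ribosomes that read through the premature stop. The wine strain reads")
print("through roughly 1.8x more often than the lab strain.")
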