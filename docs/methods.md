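# Methods

This note documents the models behind `termvar`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
can and cannot establish about real experiments.

## Readthrough quantification

Each dual-luciferase assay yields firefly and Renilla relative
luminescence units plus matched no-lysate background readings. The
pipeline subtracts background per channel (flooring negative corrected
signals at zero with a warning — luminescence cannot be negative), forms
the firefly/Renilla ratio (zero Renilla is treated as an assay failure,
not a zero), and expresses each stop-construct ratio as a percentage of
the sense-construct ratio.

Stop and sense reporters live in separate transformants, so there is no
natural per-assay pairing. By default each stop assay is normalized by
the *mean* sense ratio of the same strain; per-assay pairing by
`assay_id` is available for designs that measure both on one plate. The
reported SD is the sample SD (n−1) of the per-assay readthrough values;
a delta-method propagation from the two ratio summaries,
sd ≈ rt·√((sd_s/s)² + (sd_n/n)²), is emitted alongside for comparison
with designs that only publish ratio summaries. With a single assay the
sample SD is undefined and reported as 0 (the n < 8 QC warning fires in
that case). QC warnings, not errors, mark fewer than eight assays or
four biological replicates.

## The simulated cross

The genome is 16 chromosomes with yeast-like physical lengths
(~12.07 Mb total). Markers (default 18,000) are apportioned to
chromosomes by physical length (largest-remainder rounding) and placed
on an even grid with ±25% uniform jitter — real marker spacing is
irregular, but nothing downstream depends on more than approximate
uniformity.

Meiosis uses the Haldane map function, r = ½(1 − e^(−2d)), with genetic
distance d from a constant map rate of 0.35 cM/kb (a typical yeast
genome-wide average; configurable). Each haploid segregant starts each
chromosome from a random parent and switches parent between adjacent
markers with probability r; chromosomes assort independently and there
is no crossover interference. This makes every pairwise recombination
fraction analytically available, which the tests exploit.

The trait model is additive: percent readthrough = baseline + Σ
allele-matched QTL effects + noise, truncated at 0. The default model
has a TRM10-like locus (chr15:560,000; BY allele +0.25%) and a
SUP45-like locus (chr2:360,000; RM allele +0.35%) over a 0.2% baseline,
giving four haplotype-class means 0.2 / 0.45 / 0.55 / 0.8% — anchored to
the observed ordering in which the two mixed-parent classes are
intermediate (~0.3–0.5%) between the extreme classes (~0.2% and ~0.8%).
Only the ordering and rough scale are biologically grounded; the exact
effect sizes on the reporter scale are not published and are plain
configuration. Trait noise is additive Gaussian, SD 0.05% (assay SDs are
roughly constant on the percent scale); a multiplicative lognormal mode
exists for heteroscedastic settings. QTL positions snap to the nearest
marker.

Tail selection ranks segregants on trait plus per-cell Gaussian
measurement noise (SD 0.05%, the same order as assay noise, emulating
FACS signal spread). A tail holds round(f·N) segregants, minimum 1; from
it at most `cells_per_tail` (default 20,000) are subsampled *without*
replacement, so at the default design (N = 10,000, f = 1%) each pool is
exactly its 100 tail segregants.

Pooled probe intensities are (allele count + 0.5) per channel times an
independent lognormal multiplier with CV 0.2 (typical array noise
magnitude). The 0.5 pseudocount is ordinary additive smoothing to keep
intensities positive; the lognormal multiplier has log-scale mean zero,
so the expected log-ratio equals its noise-free value.

## Scan significance: why mock-selection nulls

At the default design each selected pool contains only ~100 segregants.
Its allele frequency at a marker unlinked to any QTL therefore drifts
around ½ with SD ≈ √(¼/100) = 0.05 — and, crucially, neighbouring
markers share the same 100 genomes, so this drift is strongly
autocorrelated along the chromosome on the centimorgan scale. Sliding-
window smoothing removes independent per-marker array noise but not this
shared drift, and a null built by per-marker sign flips (which destroys
the autocorrelation) underestimates the fluctuation of the smoothed
track and calls spurious peaks.

`null_band` therefore accepts arbitrary pre-smoothed null tracks, and
the pipeline builds them by *mock selection*: random pools of the same
size as the tails, drawn from the unselected population, pushed through
the same intensity synthesis, correction and smoothing. At markers
unlinked to the trait, a real selected pool is statistically
exchangeable with a mock pool, so these tracks carry exactly the right
null autocorrelation. The default threshold is the maximum over 100 mock
tracks of the genome-wide maximum |smoothed skew| — a familywise band
with false-call probability ≈ 1/101 per scan. Per-marker and block sign-
flip permutation modes remain available for intensity-only nulls (e.g.
when only array files, not genotypes, exist); the CLI `scan` subcommand
uses them since it sees only intensity tables.

Peak calling takes contiguous super-threshold segments, merges segments
whose gap is shorter than one window, takes each segment's extremum, and
then merges adjacent candidates topographically: a lower peak is
absorbed when the track between it and its neighbour never falls below
half the lower magnitude. The monotone decay flank of a strong QTL
flutters around any pointwise threshold; without the topographic rule a
single locus would shatter into several calls. Each peak reports its
signed extremum and the half-height flanking interval. Windows are
centered, physical-distance (bp) membership, shrink at chromosome ends,
and never span chromosomes; a constant track is a fixed point of the
smoother.

## LD statistics and the permutation null

D, D′ and r² follow the classical definitions on complete-case 2×2
haplotype counts (strains missing either call are excluded and
reported). D′ is reported as |D|/D_max because allele labelling is
arbitrary; D′ = 1 exactly when some cell of the table is empty while
both loci remain polymorphic. `reconstruct_counts` inverts printed panel
summaries (n, two allele frequencies, concordant fraction) to the unique
integer table: with row/column/diagonal totals r_A, r_B, c, the
concordant-concordant cell is (r_A + r_B + c − n)/2, and any
non-integer or negative solution is rejected with the infeasible
constraint shown. Note that summaries rounded to two digits need not
reproduce a printed r² to three digits: the canonical 63-strain example
(freqs 0.44/0.46, 76% concordance) yields the table (21, 7, 8, 27),
whose D′ = 0.5368 matches the published 0.537 while its r² = 0.2702
differs in the third digit from the published 0.266 — an input-rounding
artifact, documented rather than "corrected".

The permutation null draws locus pairs uniformly *without replacement*
among all unordered pairs whose chromosomes differ and whose minor-
allele frequencies match the target pair's within ±0.05 (both choices
configurable; the matching keeps the null pairs' attainable LD range
comparable to the target's). The empirical p-value is strict exceedance
over N pairs, p = k/N — the convention under which 9 exceedances among
1000 give exactly 0.009; tie handling is configurable (`ties="half"`).

Strain panels are drawn with independent loci within subpopulations;
subpopulation allele frequencies follow a Balding–Nichols beta model
around a shared ancestral frequency (default F = 0.2 when structured),
which induces the baseline cross-chromosome LD the permutation test must
absorb. Structure is modelled as discrete subpopulations, not admixture.
A planted pair overwrites two cross-chromosome loci with an exact target
table in random strain order, so table-level properties are exact by
construction.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible;
`stage_seed` derives independent sub-2³¹ per-stage seeds from a global
seed by hashing the stage name. The test suite exercises the full study
design — 18,000 markers × 10,000 segregants for the scan suites, 400
replicate 63-strain panels × 1000 null pairs for calibration, 50,000
meioses for recombination-fraction recovery — and completes in about a
minute; examples are scaled to a few thousand markers/segregants for
interactive readability.

## What the synthetic data does not show

The generator emulates the *statistical* structure of the experiment,
not its biology or instrumentation: no crossover interference or hotspot
structure, no real BY/RM variant coordinates, no diploid intermediates,
no sporulation or FACS gating artifacts, no array spatial effects (noise
is i.i.d. lognormal per probe after rank-invariant-style normalization
is assumed), and structured panels are caricatures of real population
history. Passing tests therefore establish that the pipeline's
inference is correct under its stated model — unbiased skews, calibrated
nulls, exact LD arithmetic — not that the model captures every feature
of real arrays or real panels. The worked-example checks (ratio
arithmetic, table reconstruction, D′, concordance, p-value convention)
are model-free and carry over directly.

## Known limitations

* The scan's familywise null band requires genotype access (or replicate
  arrays) to build mock pools; with intensity files alone the sign-flip
  null is the fallback and is anticonservative for small pools.
* `reconstruct_counts` assumes complete genotype data in the summarized
  panel.
* Peak intervals are half-height heuristics, not confidence intervals;
  no multi-QTL interval refinement is attempted.
* r² between pairs with missing data uses per-pair complete cases, so
  different pairs may rest on different strain subsets.
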