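"""Two-locus linkage disequilibrium on haploid strain panels.

Implements the classical pairwise LD statistics D, D' and r^2 from 2x2
haplotype counts, the expected haplotype concordance under independence,
an exact integer reconstruction of a 2x2 table from printed summary
statistics, and an empirical permutation test that compares an observed
locus pair against frequency-matched random pairs drawn from different
chromosomes (so that genuine LD is judged against the background level
induced by population structure alone).

Conventions: allele A/B is the BY allele at locus 1/2; D = p_AB - pA*pB;
D' = |D| / D_max (allele labelling is arbitrary, so only the magnitude is
meaningful); r^2 = D^2 / (pA qA pB qB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


class MonomorphicLocusError(ValueError):
    """LD is undefined when a locus has no variation among complete cases."""


@dataclass
class GenotypePanel:
    """Haploid strains x loci genotype matrix with locus metadata.

    Genotypes are 0 (BY), 1 (RM) or -1 (missing). ``loci`` has columns
    (chrom, pos, id), one row per locus, 1-based positions.
    """

    genotypes: np.ndarray        # int8, (n_strains, n_loci)
    strain_ids: list[str]
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[0] != len(self.strain_ids):
            raise ValueError("one row per strain required")
        if self.genotypes.shape[1] != len(self.loci):
            raise ValueError("one locus metadata row per column required")
        bad = ~np.isin(self.genotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0 (BY), 1 (RM) or -1 (missing)")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def locus_index(self, locus: int | str) -> int:
        if isinstance(locus, (int, np.integer)):
            if not 0 <= locus < self.n_loci:
                raise KeyError(f"locus index {locus} out of range")
            return int(locus)
        hits = np.flatnonzero(self.loci["id"].to_numpy() == locus)
        if hits.size == 0:
            raise KeyError(f"no locus with id {locus!r}")
        return int(hits[0])

    def by_frequency(self) -> np.ndarray:
        """Per-locus BY-allele frequency over non-missing calls (NaN if none)."""
        obs = self.genotypes != MISSING
        n_obs = obs.sum(axis=0)
        n_by = ((self.genotypes == 0) & obs).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, n_by / np.maximum(n_obs, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.by_frequency()
        return np.minimum(f, 1.0 - f)


@dataclass(frozen=True)
class HaplotypeCounts:
    """2x2 haplotype table; A/B denote the BY allele at locus A/B."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ValueError("haplotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_AB, self.n_Ab, self.n_aB, self.n_ab)


@dataclass(frozen=True)
class LdStats:
    pA: float
    pB: float
    D: float
    d_prime: float
    r2: float


@dataclass(frozen=True)
class PermutationResult:
    """Observed LD statistic against a frequency-matched cross-chromosome null."""

    observed: float
    null: np.ndarray
    n_pairs: int
    n_exceed: int
    pvalue: float
    statistic: str
    tolerance: float
    seed: int

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_pairs": self.n_pairs,
            "n_exceed": self.n_exceed,
            "pvalue": self.pvalue,
            "null_median": float(np.median(self.null)),
            "null_q99": float(np.quantile(self.null, 0.99)),
            "tolerance": self.tolerance,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def count_haplotypes(panel: GenotypePanel, locus_a: int | str,
                     locus_b: int | str) -> HaplotypeCounts:
    """Complete-case 2x2 haplotype counts for a locus pair.

    Strains missing either call are excluded and reported in
    ``n_excluded``.
    """
    ia, ib = panel.locus_index(locus_a), panel.locus_index(locus_b)
    ga, gb = panel.genotypes[:, ia], panel.genotypes[:, ib]
    ok = (ga != MISSING) & (gb != MISSING)
    a_by, b_by = ga[ok] == 0, gb[ok] == 0
    return HaplotypeCounts(
        n_AB=int(np.sum(a_by & b_by)),
        n_Ab=int(np.sum(a_by & ~b_by)),
        n_aB=int(np.sum(~a_by & b_by)),
        n_ab=int(np.sum(~a_by & ~b_by)),
        n_excluded=int(np.sum(~ok)),
    )


def ld_stats(counts: HaplotypeCounts) -> LdStats:
    """D, D' and r^2 from a 2x2 haplotype table.

    D' uses the absolute-value convention: |D| / D_max, with
    D_max = min(pA qB, qA pB) when D > 0 and min(pA pB, qA qB) when D < 0.
    Raises :class:`MonomorphicLocusError` if either locus has no variation.
    """
    n = counts.n
    if n == 0:
        raise MonomorphicLocusError("no complete-case strains")
    pA = (counts.n_AB + counts.n_Ab) / n
    pB = (counts.n_AB + counts.n_aB) / n
    qA, qB = 1.0 - pA, 1.0 - pB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicLocusError("monomorphic locus: LD undefined")
    D = counts.n_AB / n - pA * pB
    if D > 0:
        d_max = min(pA * qB, qA * pB)
    elif D < 0:
        d_max = min(pA * pB, qA * qB)
    else:
        d_max = 1.0  # D == 0 -> D' = 0 regardless
    d_prime = abs(D) / d_max
    r2 = D * D / (pA * qA * pB * qB)
    return LdStats(pA=pA, pB=pB, D=D, d_prime=d_prime, r2=r2)


def expected_concordance(pA: float, pB: float) -> float:
    """Expected same-parent haplotype fraction under independence.

    With independent loci a strain is concordant (BY-BY or RM-RM) with
    probability pA*pB + (1-pA)(1-pB).
    """
    if not (0 <= pA <= 1 and 0 <= pB <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    return pA * pB + (1.0 - pA) * (1.0 - pB)


def reconstruct_counts(n: int, freq_a: float, freq_b: float,
                       concordant_fraction: float) -> HaplotypeCounts:
    """Solve the unique integer 2x2 table matching printed summaries.

    Constraints: n_AB + n_Ab = round(freq_a * n), n_AB + n_aB =
    round(freq_b * n), n_AB + n_ab = round(concordant_fraction * n), total
    n. The linear system has a unique solution; non-integer or negative
    solutions raise with the infeasible constraint shown.
    """
    ra = round(freq_a * n)
    rb = round(freq_b * n)
    c = round(concordant_fraction * n)
    twice_ab = ra + rb + c - n
    if twice_ab % 2 != 0:
        raise ValueError(
            f"inconsistent summaries: n_AB = ({ra} + {rb} + {c} - {n})/2 is not an integer")
    n_AB = twice_ab // 2
    n_Ab, n_aB, n_ab = ra - n_AB, rb - n_AB, c - n_AB
    if min(n_AB, n_Ab, n_aB, n_ab) < 0:
        raise ValueError(
            f"inconsistent summaries: negative cell in ({n_AB}, {n_Ab}, {n_aB}, {n_ab})")
    return HaplotypeCounts(n_AB=n_AB, n_Ab=n_Ab, n_aB=n_aB, n_ab=n_ab)


# ---------------------------------------------------------------------------
# frequency-matched permutation null
# ---------------------------------------------------------------------------

def _eligible_pairs(panel: GenotypePanel, locus_a: int, locus_b: int,
                    tolerance: float) -> np.ndarray:
    """All unordered cross-chromosome pairs (x, y) with MAF(x) ~ MAF(a),
    MAF(y) ~ MAF(b), excluding the target loci themselves."""
    maf = panel.maf()
    chrom = panel.loci["chrom"].to_numpy()
    target = {locus_a, locus_b}
    ok = np.isfinite(maf)
    ok[list(target)] = False
    ea = np.flatnonzero(ok & (np.abs(maf - maf[locus_a]) <= tolerance))
    eb = np.flatnonzero(ok & (np.abs(maf - maf[locus_b]) <= tolerance))
    xx, yy = np.meshgrid(ea, eb, indexing="ij")
    xx, yy = xx.ravel(), yy.ravel()
    keep = chrom[xx] != chrom[yy]
    xx, yy = xx[keep], yy[keep]
    pairs = np.stack([np.minimum(xx, yy), np.maximum(xx, yy)], axis=1)
    return np.unique(pairs, axis=0)


def frequency_matched_pairs(panel: GenotypePanel, locus_a: int | str,
                            locus_b: int | str, n_pairs: int = 1000,
                            tolerance: float = 0.05,
                            seed: int = 0) -> np.ndarray:
    """Sample cross-chromosome locus pairs frequency-matched to the target.

    Pairs are drawn uniformly without replacement among eligible unordered
    pairs: chromosomes differ, one locus matches the minor-allele frequency
    of each target locus within ``tolerance``, and neither locus is a
    target locus. Returns an (n_pairs, 2) index array.
    """
    ia, ib = panel.locus_index(locus_a), panel.locus_index(locus_b)
    pairs = _eligible_pairs(panel, ia, ib, tolerance)
    if len(pairs) < n_pairs:
        raise ValueError(
            f"only {len(pairs)} eligible pairs for {n_pairs} requested; "
            f"increase the frequency-matching tolerance (currently {tolerance})")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(pairs), size=n_pairs, replace=False)
    return pairs[take]


def pairwise_ld(panel: GenotypePanel, pairs: np.ndarray,
                statistic: str = "r2") -> np.ndarray:
    """Vectorized D'/r^2 for many locus pairs (complete-case per pair).

    Pairs whose complete-case table is monomorphic get NaN.
    """
    if statistic not in ("r2", "dprime"):
        raise ValueError("statistic must be 'r2' or 'dprime'")
    g = panel.genotypes
    obs = (g != MISSING).astype(np.float64)
    x = ((g == 0) & (g != MISSING)).astype(np.float64)   # BY indicator
    xa, xb = x[:, pairs[:, 0]], x[:, pairs[:, 1]]
    ma, mb = obs[:, pairs[:, 0]], obs[:, pairs[:, 1]]
    both = ma * mb
    n = both.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = (xa * both).sum(axis=0) / n
        pB = (xb * both).sum(axis=0) / n
        pAB = (xa * xb * both).sum(axis=0) / n
        D = pAB - pA * pB
        qA, qB = 1.0 - pA, 1.0 - pB
        denom = pA * qA * pB * qB
        if statistic == "r2":
            vals = D * D / denom
        else:
            d_max = np.where(D >= 0, np.minimum(pA * qB, qA * pB),
                             np.minimum(pA * pB, qA * qB))
            vals = np.where(D == 0, 0.0, np.abs(D) / d_max)
        vals = np.where((n > 0) & (denom > 0), vals, np.nan)
    return vals


def empirical_pvalue(observed: float, null: np.ndarray,
                     ties: str = "strict") -> float:
    """k/N empirical p-value: fraction of null values exceeding the observed.

    ``ties='strict'`` counts only strictly greater null values (so 9
    exceedances among 1000 give p = 0.009 exactly); ``ties='half'`` adds
    half of the exact ties.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    k = float(np.sum(null > observed))
    if ties == "half":
        k += 0.5 * float(np.sum(null == observed))
    elif ties != "strict":
        raise ValueError("ties must be 'strict' or 'half'")
    return k / null.size


def permutation_pvalue(panel: GenotypePanel, locus_a: int | str,
                       locus_b: int | str, statistic: str = "r2",
                       n_pairs: int = 1000, tolerance: float = 0.05,
                       seed: int = 0, ties: str = "strict") -> PermutationResult:
    """Empirical p-value for the LD of a locus pair against matched null pairs.

    The null is the LD statistic over ``n_pairs`` frequency-matched
    cross-chromosome pairs; p = (# null strictly greater) / n_pairs,
    matching the strict-exceedance convention. Null pairs whose statistic
    is undefined (monomorphic after exclusions) are resampled away by
    construction only if their MAF was NaN; residual NaNs count as
    non-exceedances.
    """
    ia, ib = panel.locus_index(locus_a), panel.locus_index(locus_b)
    counts = count_haplotypes(panel, ia, ib)
    stats = ld_stats(counts)
    observed = stats.r2 if statistic == "r2" else stats.d_prime
    pairs = frequency_matched_pairs(panel, ia, ib, n_pairs=n_pairs,
                                    tolerance=tolerance, seed=seed)
    null = pairwise_ld(panel, pairs, statistic=statistic)
    finite_null = np.where(np.isfinite(null), null, -np.inf)
    pvalue = empirical_pvalue(observed, finite_null, ties=ties)
    return PermutationResult(
        observed=float(observed), null=null, n_pairs=n_pairs,
        n_exceed=int(np.sum(finite_null > observed)), pvalue=float(pvalue),
        statistic=statistic, tolerance=tolerance, seed=seed,
    )
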