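"""Synthetic data generation for the readthrough mapping pipeline.

This module emulates every input the analysis consumes:

* a biparental haploid yeast cross (BY x RM style) — a marker map over 16
  chromosomes and recombinant segregant genotypes under the Haldane
  (no-interference) map function,
* a two-locus additive trait model for percent stop-codon readthrough with
  opposing parental effects,
* extreme-tail selection of the segregating population (FACS-style sorting
  on a noisy per-cell signal),
* allele-specific pooled probe intensities with multiplicative lognormal
  noise, and
* structured strain panels with an optionally planted correlated locus pair
  for linkage-disequilibrium testing.

Alleles are coded ``0`` for the BY parent and ``1`` for the RM parent
throughout; segregants are haploid, so there are no heterozygotes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import GenotypePanel

BY = 0
RM = 1

#: Approximate S. cerevisiae chromosome lengths (bp), chromosomes I..XVI.
#: Used only to shape the synthetic genome; no real variant coordinates are
#: modelled.
YEAST_CHROM_LENGTHS: tuple[int, ...] = (
    230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
    562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
    1_091_291, 948_066,
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated biparental cross.

    ``map_rate_cm_per_kb`` converts physical to genetic distance; 0.35 cM/kb
    is a typical genome-wide average for S. cerevisiae.
    """

    n_markers: int = 18_000
    n_chromosomes: int = 16
    chrom_lengths: tuple[int, ...] | None = None
    map_rate_cm_per_kb: float = 0.35
    n_segregants: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers <= 0 or self.n_chromosomes <= 0 or self.n_segregants <= 0:
            raise ConfigurationError("marker, chromosome and segregant counts must be positive")
        if self.map_rate_cm_per_kb < 0:
            raise ConfigurationError("map rate must be >= 0")
        if self.chrom_lengths is not None and len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigurationError("chrom_lengths must have one entry per chromosome")
        if self.n_markers < self.n_chromosomes:
            raise ConfigurationError("need at least one marker per chromosome")

    def lengths(self) -> np.ndarray:
        if self.chrom_lengths is not None:
            arr = np.asarray(self.chrom_lengths, dtype=np.int64)
        elif self.n_chromosomes == 16:
            arr = np.asarray(YEAST_CHROM_LENGTHS, dtype=np.int64)
        else:
            # fall back to equal-sized chromosomes covering a yeast-sized genome
            arr = np.full(self.n_chromosomes, 750_000, dtype=np.int64)
        if (arr <= 0).any():
            raise ConfigurationError("chromosome lengths must be positive")
        return arr


@dataclass(frozen=True)
class MarkerMap:
    """Genome coordinate frame: one row per marker, sorted by (chrom, pos).

    Positions are 1-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray          # int, 1..n_chromosomes
    pos: np.ndarray            # int64, bp
    ids: np.ndarray            # str
    chrom_lengths: np.ndarray  # int64, bp, indexed by chrom-1
    map_rate_cm_per_kb: float

    def __post_init__(self) -> None:
        if len(self.chrom) != len(self.pos) or len(self.pos) != len(self.ids):
            raise ConfigurationError("marker map columns must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ConfigurationError("marker ids must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ConfigurationError(f"positions not strictly increasing on chromosome {c}")
            if p.min() < 1 or p.max() > self.chrom_lengths[c - 1]:
                raise ConfigurationError(f"position outside chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "id": self.ids})

    def nearest_marker(self, chrom: int, pos: int) -> int:
        """Global index of the marker nearest to (chrom, pos)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise ConfigurationError(f"no markers on chromosome {chrom}")
        return int(idx[np.argmin(np.abs(self.pos[idx] - pos))])


def _apportion(n: int, lengths: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n markers over chromosomes, >=1 each."""
    quota = n * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    base = np.maximum(base, 1)
    # distribute the remainder by largest fractional part
    while base.sum() > n:
        base[np.argmax(base)] -= 1
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - np.floor(quota)))
        for i in order[:rem]:
            base[i] += 1
    return base


def build_marker_map(config: CrossConfig) -> MarkerMap:
    """Place markers across chromosomes proportionally to physical length.

    Markers are evenly spaced within each chromosome with a small uniform
    jitter; deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lengths = config.lengths()
    per_chrom = _apportion(config.n_markers, lengths)

    chroms, positions, ids = [], [], []
    for c, (n_c, length) in enumerate(zip(per_chrom, lengths), start=1):
        spacing = length / n_c
        centers = (np.arange(n_c) + 0.5) * spacing
        jitter = rng.uniform(-0.25, 0.25, size=n_c) * spacing
        pos = np.round(centers + jitter).astype(np.int64)
        pos = np.clip(pos, 1, length)
        pos.sort()
        # enforce strict increase (ties are rare; bump minimally)
        ar = np.arange(n_c)
        pos = np.maximum.accumulate(pos - ar) + ar
        chroms.append(np.full(n_c, c, dtype=np.int64))
        positions.append(pos)
        ids.extend(f"c{c:02d}_m{i:05d}" for i in range(n_c))

    return MarkerMap(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ids=np.asarray(ids, dtype=object),
        chrom_lengths=lengths,
        map_rate_cm_per_kb=config.map_rate_cm_per_kb,
    )


# ---------------------------------------------------------------------------
# segregants and traits
# ---------------------------------------------------------------------------

@dataclass
class SegregantPopulation:
    """Haploid segregants: genotype matrix (segregants x markers) plus traits.

    Genotypes are 0 (BY) / 1 (RM); ``traits`` is percent readthrough per
    segregant, ``None`` until :func:`assign_trait` runs.
    """

    marker_map: MarkerMap
    genotypes: np.ndarray                 # uint8, (n_segregants, n_markers)
    traits: np.ndarray | None = None      # float64, (n_segregants,)

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    def by_frequency(self) -> np.ndarray:
        """Per-marker BY-allele frequency in the population."""
        return 1.0 - self.genotypes.mean(axis=0)

    def subset(self, idx: np.ndarray) -> "SegregantPopulation":
        traits = None if self.traits is None else self.traits[idx]
        return SegregantPopulation(self.marker_map, self.genotypes[idx], traits)


def haldane_r(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction r = (1 - e^(-2d)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def simulate_segregants(marker_map: MarkerMap, config: CrossConfig,
                        seed: int | None = None) -> SegregantPopulation:
    """Simulate haploid meiotic segregants chromosome by chromosome.

    Each chromosome starts from a random parent (probability 1/2) and
    switches parent between adjacent markers with the Haldane recombination
    fraction for the inter-marker genetic distance; chromosomes assort
    independently (no crossover interference).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_segregants
    blocks = []
    morgans_per_bp = marker_map.map_rate_cm_per_kb / 100.0 / 1000.0
    for c in range(1, len(marker_map.chrom_lengths) + 1):
        sl = marker_map.chrom_slice(c)
        pos = marker_map.pos[sl]
        m = len(pos)
        if m == 0:
            continue
        r = haldane_r(np.diff(pos) * morgans_per_bp)
        start = (rng.random(n) < 0.5).astype(np.uint8)
        if m > 1:
            switches = rng.random((n, m - 1)) < r[None, :]
            geno = (start[:, None] + np.concatenate(
                [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        else:
            geno = start[:, None].astype(np.int64)
        blocks.append(geno.astype(np.uint8))
    return SegregantPopulation(marker_map, np.concatenate(blocks, axis=1))


@dataclass(frozen=True)
class QtlEffect:
    """One trait locus: carrying ``allele`` at (chrom, pos) adds ``effect_pct``."""

    name: str
    chrom: int
    pos: int
    allele: str          # "BY" or "RM"
    effect_pct: float

    def __post_init__(self) -> None:
        if self.allele not in ("BY", "RM"):
            raise ConfigurationError(f"allele must be BY or RM, got {self.allele!r}")


@dataclass(frozen=True)
class TraitModel:
    """Additive two-(or k-)locus model for percent readthrough.

    trait = baseline + sum of allele-matched effects + noise, truncated at 0.
    The default noise is additive Gaussian on the percent scale; a
    multiplicative lognormal mode (CV = ``noise_sd``) is available.
    """

    baseline_pct: float = 0.2
    qtls: tuple[QtlEffect, ...] = ()
    noise_sd: float = 0.05
    noise_mode: str = "additive"   # or "lognormal"

    def __post_init__(self) -> None:
        if self.baseline_pct <= 0:
            raise ConfigurationError("baseline must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.noise_mode not in ("additive", "lognormal"):
            raise ConfigurationError("noise_mode must be 'additive' or 'lognormal'")

    def without(self, name: str) -> "TraitModel":
        """Drop one QTL — emulates a cross in which that locus is fixed."""
        kept = tuple(q for q in self.qtls if q.name != name)
        if len(kept) == len(self.qtls):
            raise KeyError(f"no QTL named {name!r}")
        return dataclasses.replace(self, qtls=kept)


def default_trait_model() -> TraitModel:
    """Opposing-effect two-locus model anchored to the four readthrough classes.

    The BY allele at the TRM10-like locus raises readthrough, the RM allele
    at the SUP45-like locus raises it; the four haplotype classes have means
    0.2 (SUP45-BY/TRM10-RM), 0.45 (both BY), 0.55 (both RM) and 0.8 percent
    (SUP45-RM/TRM10-BY).
    """
    return TraitModel(
        baseline_pct=0.2,
        qtls=(
            QtlEffect("TRM10", chrom=15, pos=560_000, allele="BY", effect_pct=0.25),
            QtlEffect("SUP45", chrom=2, pos=360_000, allele="RM", effect_pct=0.35),
        ),
        noise_sd=0.05,
    )


def assign_trait(pop: SegregantPopulation, model: TraitModel,
                 seed: int = 0) -> SegregantPopulation:
    """Fill in trait values under ``model``; returns a new population object.

    Each QTL is resolved to the nearest marker on its chromosome; a QTL on a
    chromosome with no markers is an error naming the locus.
    """
    rng = np.random.default_rng(seed)
    trait = np.full(pop.n_segregants, model.baseline_pct, dtype=float)
    for q in model.qtls:
        try:
            j = pop.marker_map.nearest_marker(q.chrom, q.pos)
        except ConfigurationError as exc:
            raise ConfigurationError(f"QTL {q.name!r} cannot be placed: {exc}") from exc
        code = BY if q.allele == "BY" else RM
        trait += q.effect_pct * (pop.genotypes[:, j] == code)
    if model.noise_sd > 0:
        if model.noise_mode == "additive":
            trait = trait + rng.normal(0.0, model.noise_sd, size=trait.shape)
        else:
            sigma = np.sqrt(np.log1p(model.noise_sd ** 2))
            trait = trait * np.exp(rng.normal(0.0, sigma, size=trait.shape))
    return dataclasses.replace(pop, traits=np.maximum(trait, 0.0))


# ---------------------------------------------------------------------------
# tail selection and pooled intensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionConfig:
    """FACS-style tail selection: rank on trait plus per-cell measurement noise."""

    tail_fraction: float = 0.01
    cells_per_tail: int = 20_000
    measurement_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.tail_fraction < 0.5:
            raise ConfigurationError("tail fraction must be in (0, 0.5)")
        if self.cells_per_tail <= 0:
            raise ConfigurationError("cells per tail must be positive")
        if self.measurement_noise_sd < 0:
            raise ConfigurationError("measurement noise sd must be >= 0")


def select_tails(pop: SegregantPopulation, sel: SelectionConfig,
                 seed: int = 0) -> tuple[SegregantPopulation, SegregantPopulation, SegregantPopulation]:
    """Select (high pool, low pool, whole pool) by rank on the noisy signal.

    The tail holds ``round(fraction * N)`` segregants (at least 1); from it,
    ``cells_per_tail`` segregants are subsampled without replacement, capped
    at the tail size. The whole pool is the unselected population.
    """
    if pop.traits is None:
        raise ValueError("population has no traits; run assign_trait first")
    n = pop.n_segregants
    if n == 0:
        raise ValueError("empty population")
    n_tail = max(1, int(round(sel.tail_fraction * n)))
    rng = np.random.default_rng(seed)
    signal = pop.traits.astype(float)
    if sel.measurement_noise_sd > 0:
        signal = signal + rng.normal(0.0, sel.measurement_noise_sd, size=n)
    order = np.argsort(signal, kind="stable")
    low_idx, high_idx = order[:n_tail], order[-n_tail:]
    take = min(sel.cells_per_tail, n_tail)
    if take < n_tail:
        high_idx = rng.choice(high_idx, size=take, replace=False)
        low_idx = rng.choice(low_idx, size=take, replace=False)
    return pop.subset(np.sort(high_idx)), pop.subset(np.sort(low_idx)), pop


@dataclass
class PoolProfile:
    """Per-marker pooled allele data: true BY frequency and noisy intensities."""

    marker_map: MarkerMap
    freq_by: np.ndarray        # (n_markers,) in [0, 1]
    intensity_by: np.ndarray   # > 0
    intensity_rm: np.ndarray   # > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.marker_map.chrom,
            "pos": self.marker_map.pos,
            "intensity_BY": self.intensity_by,
            "intensity_RM": self.intensity_rm,
        })


def synthesize_pool_intensities(pool: SegregantPopulation, noise_cv: float = 0.2,
                                pseudocount: float = 0.5, seed: int = 0) -> PoolProfile:
    """Allele-specific probe intensities proportional to pooled allele counts.

    Each channel is (count + pseudocount) times an independent lognormal
    multiplier with the given coefficient of variation; the multiplier is
    median-unbiased (log-scale mean zero), so the expected log-ratio equals
    the noise-free value. The pseudocount keeps intensities positive.
    """
    if pool.n_segregants == 0:
        raise ValueError("empty pool")
    if noise_cv < 0:
        raise ConfigurationError("noise CV must be >= 0")
    rng = np.random.default_rng(seed)
    n_rm = pool.genotypes.sum(axis=0, dtype=np.int64)
    n_by = pool.n_segregants - n_rm
    base_by = n_by + pseudocount
    base_rm = n_rm + pseudocount
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        base_by = base_by * np.exp(rng.normal(0.0, sigma, size=base_by.shape))
        base_rm = base_rm * np.exp(rng.normal(0.0, sigma, size=base_rm.shape))
    return PoolProfile(
        marker_map=pool.marker_map,
        freq_by=n_by / pool.n_segregants,
        intensity_by=np.asarray(base_by, dtype=float),
        intensity_rm=np.asarray(base_rm, dtype=float),
    )


# ---------------------------------------------------------------------------
# strain panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPair:
    """A locus pair (different chromosomes) forced to an exact 2x2 haplotype table.

    ``table`` is (n_AB, n_Ab, n_aB, n_ab) with A/B the BY alleles at loci a/b.
    """

    locus_a: int
    locus_b: int
    table: tuple[int, int, int, int]


@dataclass(frozen=True)
class PanelConfig:
    """Structured strain-panel generator configuration.

    Subpopulation allele frequencies follow a Balding-Nichols beta model
    around a shared ancestral frequency; with one subpopulation (or fst=0)
    loci are independent draws at a common frequency.
    """

    n_strains: int = 63
    n_loci: int = 2_000
    n_chromosomes: int = 16
    n_subpops: int = 1
    subpop_props: tuple[float, ...] | None = None
    fst: float = 0.2
    freq_range: tuple[float, float] = (0.05, 0.95)
    planted: PlantedPair | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains <= 0 or self.n_loci <= 0 or self.n_subpops <= 0:
            raise ConfigurationError("counts must be positive")
        if self.subpop_props is not None:
            if len(self.subpop_props) != self.n_subpops:
                raise ConfigurationError("one proportion per subpopulation required")
            if abs(sum(self.subpop_props) - 1.0) > 1e-9:
                raise ConfigurationError("subpopulation proportions must sum to 1")
        if not 0 <= self.fst < 1:
            raise ConfigurationError("fst must be in [0, 1)")


def simulate_strain_panel(config: PanelConfig) -> GenotypePanel:
    """Draw a haploid strain panel; loci independent within subpopulations.

    Population structure (divergent subpopulation frequencies) induces
    baseline LD between unlinked loci. If a planted pair is configured, its
    haplotypes are overwritten to match the target 2x2 table exactly
    (assigned to strains in random order).
    """
    rng = np.random.default_rng(config.seed)
    mmap = build_marker_map(CrossConfig(
        n_markers=config.n_loci, n_chromosomes=config.n_chromosomes,
        n_segregants=1, seed=config.seed,
    ))
    lo, hi = config.freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)

    props = (np.full(config.n_subpops, 1.0 / config.n_subpops)
             if config.subpop_props is None else np.asarray(config.subpop_props))
    counts = _apportion(config.n_strains, props * 1000 + 1e-9)
    membership = np.repeat(np.arange(config.n_subpops), counts)

    if config.n_subpops > 1 and config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_sub = rng.beta(a[None, :], b[None, :],
                         size=(config.n_subpops, config.n_loci))
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))

    # p_sub is the BY-allele frequency; genotype 0 = BY, 1 = RM
    u = rng.random((config.n_strains, config.n_loci))
    genotypes = (u >= p_sub[membership]).astype(np.int8)

    if config.planted is not None:
        pl = config.planted
        chrom = mmap.chrom
        if chrom[pl.locus_a] == chrom[pl.locus_b]:
            raise ConfigurationError("planted pair loci must be on distinct chromosomes")
        if sum(pl.table) != config.n_strains:
            raise ConfigurationError(
                f"planted table total {sum(pl.table)} != n_strains {config.n_strains}")
        n_ab_, n_aB_, n_Ab_, n_AB_ = pl.table[3], pl.table[2], pl.table[1], pl.table[0]
        hap_a = np.concatenate([
            np.zeros(n_AB_ + n_Ab_, dtype=np.int8),   # BY at locus a
            np.ones(n_aB_ + n_ab_, dtype=np.int8),
        ])
        hap_b = np.concatenate([
            np.zeros(n_AB_, dtype=np.int8), np.ones(n_Ab_, dtype=np.int8),
            np.zeros(n_aB_, dtype=np.int8), np.ones(n_ab_, dtype=np.int8),
        ])
        order = rng.permutation(config.n_strains)
        genotypes[:, pl.locus_a] = hap_a[order]
        genotypes[:, pl.locus_b] = hap_b[order]

    strain_ids = [f"strain{i:03d}" for i in range(config.n_strains)]
    return GenotypePanel(genotypes=genotypes, strain_ids=strain_ids,
                         loci=mmap.to_frame())
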