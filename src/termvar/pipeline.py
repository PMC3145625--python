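"""End-to-end orchestration of the synthetic X-QTL experiment.

Glues the generator to the scan: simulate a cross, assign traits, select
phenotypic tails, synthesize pooled array intensities, compute and smooth
the background-corrected skew, build an empirical null band, and call
peaks. The null band here comes from *mock selections* — random unselected
pools of the same size as the phenotypic tails — which reproduce both the
array intensity noise and the along-chromosome allele-frequency drift of a
finite pool, the two noise sources a real selected pool carries at
non-QTL loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scan as _scan
from .simulate import (
    CrossConfig, MarkerMap, SegregantPopulation, SelectionConfig, TraitModel,
    build_marker_map, assign_trait, select_tails, simulate_segregants,
    synthesize_pool_intensities,
)


@dataclass
class ScanResult:
    """One selected-pool scan: smoothed track, null threshold, called peaks."""

    track: pd.DataFrame
    threshold: float
    peaks: list


@dataclass
class XqtlExperiment:
    """High- and low-tail scans of one simulated cross, plus provenance."""

    marker_map: MarkerMap
    high: ScanResult
    low: ScanResult
    n_segregants: int
    pool_size: int
    seed: int


def simulate_cross(config: CrossConfig, model: TraitModel,
                   seed: int = 0) -> SegregantPopulation:
    """Marker map + segregants + traits in one call."""
    mmap = build_marker_map(config)
    pop = simulate_segregants(mmap, config, seed=seed)
    return assign_trait(pop, model, seed=seed + 1)


def mock_selection_null(pop: SegregantPopulation, pool_size: int,
                        whole_delta: np.ndarray, noise_cv: float,
                        n_null: int = 100, window_bp: int = 40_000,
                        seed: int = 0) -> list[np.ndarray]:
    """Smoothed null tracks from random (selection-free) pools.

    Each null track draws ``pool_size`` segregants without replacement,
    synthesizes noisy intensities, corrects against the provided
    whole-population log10 intensity difference and smooths — an honest
    null for "no locus is under selection".
    """
    rng = np.random.default_rng(seed)
    base = pd.DataFrame({"chrom": pop.marker_map.chrom, "pos": pop.marker_map.pos})
    nulls = []
    for _ in range(n_null):
        idx = rng.choice(pop.n_segregants, size=pool_size, replace=False)
        prof = synthesize_pool_intensities(
            pop.subset(idx), noise_cv=noise_cv,
            seed=int(rng.integers(2 ** 31)))
        delta = np.log10(prof.intensity_by) - np.log10(prof.intensity_rm)
        base["corrected"] = delta - whole_delta
        nulls.append(_scan.smooth(base, window_bp=window_bp)["smoothed"].to_numpy())
    return nulls


def run_xqtl(pop: SegregantPopulation,
             selection: SelectionConfig | None = None,
             noise_cv: float = 0.2, window_bp: int = 40_000,
             n_null: int = 100, null_quantile: float = 1.0,
             seed: int = 0) -> XqtlExperiment:
    """Select tails, scan both pools, and call peaks against a mock null.

    The threshold is the ``null_quantile`` quantile (default: the maximum)
    of the genome-wide max |smoothed skew| over ``n_null`` mock-selection
    tracks, i.e. a familywise band.
    """
    selection = selection or SelectionConfig()
    high, low, whole = select_tails(pop, selection, seed=seed)
    whole_prof = synthesize_pool_intensities(whole, noise_cv=noise_cv, seed=seed + 1)
    whole_frame = whole_prof.to_frame()
    whole_delta = np.log10(whole_prof.intensity_by) - np.log10(whole_prof.intensity_rm)

    results = {}
    for name, pool, pool_seed in (("high", high, seed + 2), ("low", low, seed + 3)):
        prof = synthesize_pool_intensities(pool, noise_cv=noise_cv, seed=pool_seed)
        track = _scan.compute_skew(prof.to_frame(), whole_frame)
        results[name] = _scan.smooth(track, window_bp=window_bp)

    nulls = mock_selection_null(pop, pool_size=high.n_segregants,
                                whole_delta=whole_delta, noise_cv=noise_cv,
                                n_null=n_null, window_bp=window_bp,
                                seed=seed + 4)
    threshold = _scan.null_band(nulls, quantile=null_quantile, family="max")

    out = {}
    for name in ("high", "low"):
        peaks = _scan.call_peaks(results[name], threshold, window_bp=window_bp)
        out[name] = ScanResult(track=results[name], threshold=threshold, peaks=peaks)
    return XqtlExperiment(marker_map=pop.marker_map, high=out["high"],
                          low=out["low"], n_segregants=pop.n_segregants,
                          pool_size=high.n_segregants, seed=seed)
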