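"""Cross simulator: marker maps, Haldane meiosis, traits, selection, panels."""

import numpy as np
import pytest
from scipy import stats

import termvar as tv
from termvar.simulate import (
    BY, RM, ConfigurationError, CrossConfig, PanelConfig, PlantedPair,
    QtlEffect, SelectionConfig, TraitModel, assign_trait, build_marker_map,
    default_trait_model, haldane_r, select_tails, simulate_segregants,
    simulate_strain_panel, synthesize_pool_intensities,
)
from termvar.ld import count_haplotypes, pairwise_ld


class TestMarkerMap:
    def test_total_marker_count_is_exact(self):
        mmap = build_marker_map(CrossConfig(n_markers=18_000, seed=0))
        assert mmap.n_markers == 18_000
        assert len(np.unique(mmap.chrom)) == 16

    def test_one_marker_per_equal_chromosome(self):
        cfg = CrossConfig(n_markers=16, chrom_lengths=(100_000,) * 16)
        mmap = build_marker_map(cfg)
        assert np.array_equal(np.sort(mmap.chrom), np.arange(1, 17))

    def test_same_seed_gives_identical_maps(self):
        a = build_marker_map(CrossConfig(n_markers=500, seed=3))
        b = build_marker_map(CrossConfig(n_markers=500, seed=3))
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.chrom, b.chrom)

    def test_markers_proportional_to_length(self):
        mmap = build_marker_map(CrossConfig(n_markers=18_000, seed=0))
        counts = np.bincount(mmap.chrom)[1:]
        expected = 18_000 * mmap.chrom_lengths / mmap.chrom_lengths.sum()
        assert np.abs(counts - expected).max() <= 2

    def test_invariants_positions_strictly_increasing_in_bounds(self):
        mmap = build_marker_map(CrossConfig(n_markers=2_000, seed=5))
        for c in range(1, 17):
            p = mmap.pos[mmap.chrom == c]
            assert (np.diff(p) > 0).all()
            assert p.min() >= 1 and p.max() <= mmap.chrom_lengths[c - 1]
        assert len(set(mmap.ids)) == mmap.n_markers

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            CrossConfig(n_markers=0)


class TestMeiosis:
    def test_haldane_limits(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(50.0) == pytest.approx(0.5)

    def test_adjacent_markers_at_zero_genetic_distance_always_identical(self):
        # zero map rate makes every inter-marker distance 0 Morgans
        cfg0 = CrossConfig(n_markers=2, n_chromosomes=1, chrom_lengths=(10_000,),
                           n_segregants=500, map_rate_cm_per_kb=0.0, seed=1)
        pop = simulate_segregants(build_marker_map(cfg0), cfg0)
        assert (pop.genotypes[:, 0] == pop.genotypes[:, 1]).all()

    def test_marginal_by_frequency_near_half(self):
        cfg = CrossConfig(n_markers=200, n_segregants=10_000, seed=2)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        freq = pop.by_frequency()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 10_000, 0.5) / 10_000
        assert freq.min() >= lo - 1e-12 and freq.max() <= hi + 1e-12

    def test_recombination_fraction_matches_haldane_closed_form(self):
        # two markers 10 kb apart at 0.35 cM/kb: r = (1 - e^-0.07)/2 = 0.0338
        cfg = CrossConfig(n_markers=2, n_chromosomes=1, chrom_lengths=(20_000,),
                          n_segregants=50_000, seed=4)
        mmap = build_marker_map(cfg)
        mmap = tv.MarkerMap(chrom=mmap.chrom, pos=np.array([5_000, 15_000]),
                            ids=mmap.ids, chrom_lengths=mmap.chrom_lengths,
                            map_rate_cm_per_kb=0.35)
        pop = simulate_segregants(mmap, cfg)
        r_hat = float(np.mean(pop.genotypes[:, 0] != pop.genotypes[:, 1]))
        r_true = float(haldane_r(10 * 0.35 / 100))
        ci = stats.binom.ppf([0.0005, 0.9995], 50_000, r_true) / 50_000
        assert ci[0] <= r_hat <= ci[1]

    def test_deterministic_for_fixed_seed(self):
        cfg = CrossConfig(n_markers=300, n_segregants=100, seed=6)
        mmap = build_marker_map(cfg)
        a = simulate_segregants(mmap, cfg, seed=9)
        b = simulate_segregants(mmap, cfg, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)


class TestTraitModel:
    def test_zero_noise_zero_effects_gives_baseline(self):
        cfg = CrossConfig(n_markers=100, n_segregants=50, seed=1)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = TraitModel(baseline_pct=0.3, noise_sd=0.0)
        pop = assign_trait(pop, model)
        assert np.allclose(pop.traits, 0.3)

    def test_single_qtl_zero_noise_gives_two_values(self):
        cfg = CrossConfig(n_markers=100, n_segregants=200, seed=1)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = TraitModel(baseline_pct=0.3, noise_sd=0.0, qtls=(
            QtlEffect("q", chrom=1, pos=100_000, allele="BY", effect_pct=0.3),))
        pop = assign_trait(pop, model)
        vals = np.unique(pop.traits)
        assert len(vals) == 2 and vals[1] - vals[0] == pytest.approx(0.3)

    def test_default_model_four_ordered_class_means(self):
        cfg = CrossConfig(n_markers=2_000, n_segregants=10_000, seed=2)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = default_trait_model()
        noise_free = TraitModel(baseline_pct=model.baseline_pct,
                                qtls=model.qtls, noise_sd=0.0)
        pop = assign_trait(pop, noise_free)
        j_t = pop.marker_map.nearest_marker(15, 560_000)
        j_s = pop.marker_map.nearest_marker(2, 360_000)
        t_by = pop.genotypes[:, j_t] == BY
        s_by = pop.genotypes[:, j_s] == BY
        means = {
            "sBY_tRM": pop.traits[s_by & ~t_by].mean(),
            "both_BY": pop.traits[s_by & t_by].mean(),
            "both_RM": pop.traits[~s_by & ~t_by].mean(),
            "sRM_tBY": pop.traits[~s_by & t_by].mean(),
        }
        assert means["sBY_tRM"] == pytest.approx(0.2)
        assert means["both_BY"] == pytest.approx(0.45)
        assert means["both_RM"] == pytest.approx(0.55)
        assert means["sRM_tBY"] == pytest.approx(0.8)

    def test_class_means_recovered_within_standard_error_with_noise(self):
        cfg = CrossConfig(n_markers=500, n_segregants=10_000, seed=3)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = default_trait_model()
        pop = assign_trait(pop, model, seed=4)
        j_t = pop.marker_map.nearest_marker(15, 560_000)
        t_by = pop.genotypes[:, j_t] == BY
        for mask, expected in ((t_by, (0.45 + 0.8) / 2), (~t_by, (0.2 + 0.55) / 2)):
            se = pop.traits[mask].std(ddof=1) / np.sqrt(mask.sum())
            assert abs(pop.traits[mask].mean() - expected) < 4 * se

    def test_off_map_qtl_error_names_locus(self):
        cfg = CrossConfig(n_markers=20, n_chromosomes=2,
                          chrom_lengths=(100_000, 100_000), n_segregants=10, seed=1)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = TraitModel(qtls=(QtlEffect("ghost", chrom=9, pos=1, allele="BY",
                                           effect_pct=0.1),))
        with pytest.raises(ConfigurationError, match="ghost"):
            assign_trait(pop, model)


class TestSelectTails:
    def _pop(self, traits):
        cfg = CrossConfig(n_markers=10, n_chromosomes=1,
                          chrom_lengths=(100_000,), n_segregants=len(traits),
                          seed=0)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        pop.traits = np.asarray(traits, dtype=float)
        return pop

    def test_one_percent_of_100_is_one_segregant(self):
        pop = self._pop(np.arange(100.0))
        sel = SelectionConfig(tail_fraction=0.01, measurement_noise_sd=0.0)
        high, low, whole = select_tails(pop, sel)
        assert high.n_segregants == low.n_segregants == 1
        assert whole.n_segregants == 100

    def test_zero_noise_selects_exact_rank_extremes(self):
        traits = np.arange(200.0)
        pop = self._pop(traits)
        sel = SelectionConfig(tail_fraction=0.05, measurement_noise_sd=0.0)
        high, low, _ = select_tails(pop, sel)
        assert set(high.traits) == set(traits[-10:])
        assert set(low.traits) == set(traits[:10])

    def test_quantile_bracketing(self):
        rng = np.random.default_rng(11)
        pop = self._pop(rng.normal(size=5_000))
        sel = SelectionConfig(tail_fraction=0.02, measurement_noise_sd=0.0)
        high, low, whole = select_tails(pop, sel)
        assert high.traits.min() >= np.quantile(whole.traits, 0.98) - 1e-9
        assert low.traits.max() <= np.quantile(whole.traits, 0.02) + 1e-9

    def test_qtl_allele_enrichment_symmetric_in_tails(self):
        # brute-force oracle on a 2-marker toy cross: +BY effect at marker 0
        cfg = CrossConfig(n_markers=2, n_chromosomes=2,
                          chrom_lengths=(50_000, 50_000), n_segregants=2_000, seed=5)
        pop = simulate_segregants(build_marker_map(cfg), cfg)
        model = TraitModel(baseline_pct=0.3, noise_sd=0.0, qtls=(
            QtlEffect("q", chrom=1, pos=25_000, allele="BY", effect_pct=0.2),))
        pop = assign_trait(pop, model)
        sel = SelectionConfig(tail_fraction=0.1, measurement_noise_sd=0.0)
        high, low, whole = select_tails(pop, sel)
        f_high = 1 - high.genotypes[:, 0].mean()
        f_low = 1 - low.genotypes[:, 0].mean()
        f_whole = 1 - whole.genotypes[:, 0].mean()
        assert f_high == 1.0 and f_low == 0.0
        assert abs((f_high - f_whole) + (f_low - f_whole)) < 0.1

    def test_cells_per_tail_caps_at_tail_size(self):
        pop = self._pop(np.arange(1_000.0))
        sel = SelectionConfig(tail_fraction=0.1, cells_per_tail=30,
                              measurement_noise_sd=0.0)
        high, low, _ = select_tails(pop, sel, seed=2)
        assert high.n_segregants == low.n_segregants == 30
        assert len(set(map(float, high.traits))) == 30  # without replacement


class TestPoolIntensities:
    def _pool(self, genotypes):
        cfg = CrossConfig(n_markers=genotypes.shape[1], n_chromosomes=1,
                          chrom_lengths=(100_000,), n_segregants=1, seed=0)
        mmap = build_marker_map(cfg)
        return tv.SegregantPopulation(mmap, np.asarray(genotypes, dtype=np.uint8))

    def test_balanced_pool_no_noise_equal_intensities(self):
        pool = self._pool(np.array([[0, 0], [1, 1]]))
        prof = synthesize_pool_intensities(pool, noise_cv=0.0)
        assert np.allclose(prof.intensity_by, prof.intensity_rm)

    def test_all_by_pool_pseudocount_arithmetic(self):
        pool = self._pool(np.zeros((20, 3)))
        prof = synthesize_pool_intensities(pool, noise_cv=0.0)
        ratio = np.log10(prof.intensity_by / prof.intensity_rm)
        assert np.allclose(ratio, np.log10(20.5 / 0.5))

    def test_log_ratio_unbiased_over_noise_draws(self):
        pool = self._pool(np.array([[0] * 5] * 15 + [[1] * 5] * 5))
        noise_free = np.log10(15.5 / 5.5)
        draws = [np.log10(p.intensity_by / p.intensity_rm).mean()
                 for p in (synthesize_pool_intensities(pool, noise_cv=0.3, seed=s)
                           for s in range(1_000))]
        assert np.mean(draws) == pytest.approx(noise_free, abs=3 * np.std(draws) / np.sqrt(1000))

    def test_negative_cv_rejected(self):
        pool = self._pool(np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            synthesize_pool_intensities(pool, noise_cv=-0.1)


class TestStrainPanel:
    def test_planted_table_recovered_exactly(self):
        cfg = PanelConfig(n_loci=300, planted=PlantedPair(5, 250, (21, 7, 8, 27)),
                          seed=1)
        panel = simulate_strain_panel(cfg)
        assert count_haplotypes(panel, 5, 250).as_tuple() == (21, 7, 8, 27)

    def test_planted_pair_must_span_chromosomes(self):
        with pytest.raises(ConfigurationError, match="distinct chromosomes"):
            simulate_strain_panel(PanelConfig(
                n_loci=300, planted=PlantedPair(0, 1, (21, 7, 8, 27))))

    def test_planted_table_total_must_match_strains(self):
        with pytest.raises(ConfigurationError, match="n_strains"):
            simulate_strain_panel(PanelConfig(
                n_loci=300, planted=PlantedPair(5, 250, (21, 7, 8, 20))))

    def test_unstructured_cross_chromosome_r2_near_1_over_n(self):
        # sample r^2 under independence has expectation ~ 1/n
        panel = simulate_strain_panel(PanelConfig(n_loci=800, seed=2))
        chrom = panel.loci["chrom"].to_numpy()
        rng = np.random.default_rng(3)
        a = rng.integers(0, 800, 6_000)
        b = rng.integers(0, 800, 6_000)
        keep = chrom[a] != chrom[b]
        vals = pairwise_ld(panel, np.stack([a[keep], b[keep]], axis=1))
        vals = vals[np.isfinite(vals)]
        assert np.mean(vals) == pytest.approx(1 / 63, rel=0.25)

    def test_structure_raises_background_ld(self):
        flat = simulate_strain_panel(PanelConfig(n_loci=600, seed=4))
        structured = simulate_strain_panel(PanelConfig(
            n_loci=600, n_subpops=3, fst=0.25, seed=4))
        rng = np.random.default_rng(5)
        a = rng.integers(0, 600, 4_000)
        b = rng.integers(0, 600, 4_000)
        def med(panel):
            chrom = panel.loci["chrom"].to_numpy()
            keep = chrom[a] != chrom[b]
            v = pairwise_ld(panel, np.stack([a[keep], b[keep]], axis=1))
            return np.nanmedian(v)
        assert med(structured) > med(flat)

    def test_generator_bit_reproducible(self):
        a = simulate_strain_panel(PanelConfig(n_loci=200, n_subpops=2, seed=6))
        b = simulate_strain_panel(PanelConfig(n_loci=200, n_subpops=2, seed=6))
        assert np.array_equal(a.genotypes, b.genotypes)


class TestEndToEndEnrichment:
    def test_high_tail_enriched_for_both_increasing_alleles(self, small_cross):
        # opposing-effect model: high tail carries TRM10-BY and SUP45-RM
        pop, model = small_cross
        noise_free = assign_trait(pop, TraitModel(
            baseline_pct=model.baseline_pct, qtls=model.qtls, noise_sd=0.0), seed=1)
        sel = SelectionConfig(tail_fraction=0.01, measurement_noise_sd=0.0)
        high, _, whole = select_tails(noise_free, sel, seed=2)
        j_t = pop.marker_map.nearest_marker(15, 560_000)
        j_s = pop.marker_map.nearest_marker(2, 360_000)
        assert (high.genotypes[:, j_t] == BY).mean() > 0.9
        assert (high.genotypes[:, j_s] == RM).mean() > 0.9
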