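"""Forward Wright-Fisher engine: scenarios, DFE, reproduction, rescaling."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from rohscape.simulator import (DfeModel, RecombRegions, SimPopulation,
                                SimScenario, SimulationError, _Registry,
                                build_scenario, draw_mutation,
                                equilibrium_population, pairwise_diversity,
                                run_simulation, step_generation)


class TestRecombRegions:
    def test_constant_map_total_morgans(self):
        recomb = RecombRegions.constant(100_000_000, 1.038)
        assert recomb.total_morgans() == pytest.approx(1.038)

    def test_ten_region_map_edges_and_cm(self):
        recomb = RecombRegions.ten_region(100_000_000)
        assert recomb.region_ends_bp[0] == pytest.approx(10_000_000)
        assert recomb.region_ends_bp[-1] == pytest.approx(100_000_000)
        # cM at the first region boundary: 10 Mb x 1.75 cM/Mb
        assert recomb.cm_at(np.array([10_000_000]))[0] == pytest.approx(17.5)
        assert recomb.cm_at(np.array([0]))[0] == 0.0

    def test_scaled_multiplies_rates_only(self):
        recomb = RecombRegions.constant(1_000_000, 1.0).scaled(10)
        assert recomb.total_morgans() == pytest.approx(0.1)
        assert recomb.chromosome_length == 1_000_000

    def test_crossover_count_matches_map_length(self):
        recomb = RecombRegions.constant(100_000_000, 1.038)
        rng = np.random.default_rng(0)
        counts = [len(recomb.sample_crossovers(rng)) for _ in range(3000)]
        assert np.mean(counts) == pytest.approx(1.038, abs=0.06)

    def test_crossovers_concentrate_in_high_rate_regions(self):
        recomb = RecombRegions((5_000_000, 10_000_000), (9.0, 1.0))
        rng = np.random.default_rng(1)
        pos = np.concatenate([recomb.sample_crossovers(rng) for _ in range(2000)])
        assert (pos < 5_000_000).mean() == pytest.approx(0.9, abs=0.03)

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            RecombRegions((5_000_000, 4_000_000), (1.0, 1.0))
        with pytest.raises(ValueError):
            RecombRegions((1_000_000,), (-0.5,))


class TestBuildScenario:
    def test_rum_parameterisation(self):
        scen = build_scenario("rum", 1)
        assert scen.epochs == ((0, 7500), (75_000, 100))
        assert scen.n_generations_total == 75_030
        assert scen.recomb.rates_cm_per_mb == (1.038,)
        assert scen.sample_size == 100
        assert scen.dfe.is_neutral

    def test_severe_model4_deleterious_mean(self):
        scen = build_scenario("severe_bottleneck", 4)
        dfe = scen.dfe
        assert dfe.deleterious_mean_s * dfe.selection_multiplier == \
            pytest.approx(-0.05)
        assert dfe.beneficial_mean_s * dfe.selection_multiplier == \
            pytest.approx(0.005)
        assert scen.epochs == ((0, 7500), (75_000, 10), (75_005, 100))

    def test_no_bottleneck_rescaled_by_ten(self):
        scen = build_scenario("no_bottleneck", 2, rescale_Q=10)
        assert scen.burn_in_ne == 750
        assert scen.burn_in_generations == round(75_030 / 10)
        assert scen.burn_in_mutation_rate == pytest.approx(1e-7)
        assert scen.burn_in_recomb.rates_cm_per_mb[0] == pytest.approx(17.5)
        assert scen.dfe.is_neutral
        assert len(scen.recomb.rates_cm_per_mb) == 10

    def test_endgame_sizes(self):
        assert build_scenario("rum", 1).endgame_sizes() == [100] * 31
        severe = build_scenario("severe_bottleneck", 1).endgame_sizes()
        assert severe[:5] == [10] * 5 and severe[5:] == [100] * 26
        assert build_scenario("no_bottleneck", 1).endgame_sizes() == []

    def test_unknown_scenario_or_model_rejected(self):
        with pytest.raises(ValueError):
            build_scenario("island", 1)
        with pytest.raises(ValueError):
            build_scenario("rum", 5)


class TestDfe:
    def test_neutral_draw(self):
        rng = np.random.default_rng(0)
        assert draw_mutation(DfeModel.neutral(), rng) == (0.0, 0.5)

    def test_class_frequencies_match_3_1_10(self):
        rng = np.random.default_rng(1)
        s, h = DfeModel.deer_default().draw(100_000, rng)
        p_neutral = (s == 0).mean()
        p_beneficial = (s > 0).mean()
        p_deleterious = (s < 0).mean()
        assert p_neutral == pytest.approx(3 / 14, abs=0.01)
        assert p_beneficial == pytest.approx(1 / 14, abs=0.01)
        assert p_deleterious == pytest.approx(10 / 14, abs=0.01)

    def test_deleterious_mean_selection_coefficient(self):
        rng = np.random.default_rng(2)
        s, h = DfeModel.deer_default().draw(200_000, rng)
        dele = s[s < 0]
        # gamma with shape 0.2 has sd = mean/sqrt(0.2); large-n Monte Carlo
        assert dele.mean() == pytest.approx(-0.01, abs=0.0005)
        assert set(np.unique(h[s < 0])) == {0.1}
        assert set(np.unique(h[s > 0])) == {0.5}

    def test_multiplier_scales_selection_not_weights(self):
        rng = np.random.default_rng(3)
        s5, _ = DfeModel.deer_default(5.0).draw(100_000, rng)
        assert s5[s5 < 0].mean() == pytest.approx(-0.05, rel=0.1)


def _two_allele_population(n_individuals, n_derived_haps, token=123 << 21,
                           selected=False, s=-1.0, h=0.5):
    """Population where the first haplotypes carry one derived mutation."""
    empty = np.empty(0, dtype=np.int64)
    carrier = np.array([token], dtype=np.int64)
    haps = [carrier.copy() if k < n_derived_haps else empty.copy()
            for k in range(2 * n_individuals)]
    sel = [carrier.copy() if (selected and k < n_derived_haps) else empty.copy()
           for k in range(2 * n_individuals)]
    registry = _Registry()
    if selected:
        registry.add(np.array([token], dtype=np.int64), np.array([s]),
                     np.array([h]))
    return SimPopulation(haplotypes=haps, selected=sel, registry=registry)


NO_RECOMB = RecombRegions((1_000_000,), (0.0,))


class TestStepGeneration:
    def test_new_mutation_count_matches_mu_L(self):
        pop = SimPopulation.founders(200)
        rng = np.random.default_rng(4)
        nxt = step_generation(pop, 200, 1e-8, NO_RECOMB, DfeModel.neutral(),
                              rng, chromosome_length=100_000_000)
        per_gamete = [len(h) for h in nxt.haplotypes]
        assert np.mean(per_gamete) == pytest.approx(1.0, abs=0.15)

    def test_zero_fitness_homozygotes_never_reproduce(self):
        # all but one individual are derived-homozygous lethals
        pop = _two_allele_population(20, 38, selected=True, s=-1.0)
        rng = np.random.default_rng(5)
        nxt = step_generation(pop, 50, 0.0, NO_RECOMB, DfeModel.neutral(),
                              rng, chromosome_length=1_000_000)
        # only the wild-type individual could be a parent -> allele extinct
        assert all(len(h) == 0 for h in nxt.haplotypes)

    def test_all_zero_fitness_population_signals_failure(self):
        pop = _two_allele_population(5, 10, selected=True, s=-1.0)
        with pytest.raises(SimulationError, match="fitness"):
            step_generation(pop, 5, 0.0, NO_RECOMB, DfeModel.neutral(),
                            np.random.default_rng(6), 1_000_000)

    def test_neutral_single_site_matches_binomial_wright_fisher(self):
        """Allele-count transition distribution vs the binomial oracle."""
        ne, k0, reps = 10, 8, 2000
        counts = np.zeros(2 * ne + 1, dtype=int)
        rng = np.random.default_rng(7)
        pop = _two_allele_population(ne, k0)
        for _ in range(reps):
            nxt = step_generation(pop, ne, 0.0, NO_RECOMB, DfeModel.neutral(),
                                  rng, 1_000_000)
            counts[sum(len(h) for h in nxt.haplotypes)] += 1
        expected = sp_stats.binom.pmf(np.arange(2 * ne + 1), 2 * ne,
                                      k0 / (2 * ne)) * reps
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 \
            / max(expected[~keep].sum(), 1e-9)
        p = sp_stats.chi2.sf(chi2, keep.sum())  # df ~ bins - 1, conservative
        assert p > 1e-3

    def test_heterozygote_advantage_of_parent_choice(self):
        # derived het individuals with s>0 reproduce more often
        pop = _two_allele_population(100, 50, selected=True, s=1.0, h=1.0)
        rng = np.random.default_rng(8)
        freqs = []
        for _ in range(50):
            nxt = step_generation(pop, 100, 0.0, NO_RECOMB, DfeModel.neutral(),
                                  rng, 1_000_000)
            freqs.append(sum(len(h) for h in nxt.haplotypes) / 200)
        assert np.mean(freqs) > 0.3  # neutral expectation 0.25


class TestPopulation:
    def test_prune_fixed_counts_and_removes(self):
        token = 500 << 21
        pop = _two_allele_population(4, 8)  # fixed in all 8 haplotypes
        assert pop.prune_fixed() == 1
        assert pop.n_fixed_pruned == 1
        assert all(len(h) == 0 for h in pop.haplotypes)
        assert pop.prune_fixed() == 0

    def test_fitness_hom_vs_het_factors(self):
        pop = _two_allele_population(3, 2, selected=True, s=-0.5, h=0.2)
        # individual 0 is derived hom (1-0.5), 1 and 2 are wild type
        w = pop.fitness()
        assert w[0] == pytest.approx(0.5)
        assert w[1] == w[2] == 1.0
        het = _two_allele_population(3, 1, selected=True, s=-0.5, h=0.2)
        assert het.fitness()[0] == pytest.approx(1 - 0.2 * 0.5)


class TestRunSimulation:
    def test_same_seed_identical_output(self):
        scen = build_scenario("rum", 1, rescale_Q=25, seed=31,
                              chromosome_length=2_000_000)
        a = run_simulation(scen)
        b = run_simulation(scen)
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        np.testing.assert_array_equal(a.marker_map.bp_pos, b.marker_map.bp_pos)

    def test_rum_outputs_exactly_100_individuals(self):
        scen = build_scenario("rum", 1, rescale_Q=25, seed=32,
                              chromosome_length=2_000_000)
        result = run_simulation(scen)
        assert result.genotypes.n_individuals == 100
        assert result.haplotypes.alleles.shape[0] == 200

    def test_output_sites_are_segregating_and_sorted(self):
        scen = build_scenario("severe_bottleneck", 1, rescale_Q=25, seed=33,
                              chromosome_length=2_000_000)
        result = run_simulation(scen)
        freqs = result.genotypes.calls.sum(axis=0) / (2.0 * 100)
        assert ((freqs > 0) & (freqs < 1)).all()
        assert (np.diff(result.marker_map.bp_pos) > 0).all()
        # cM positions follow the nominal (unrescaled) map
        expected_cm = result.marker_map.bp_pos * 1.038e-6
        np.testing.assert_allclose(result.marker_map.cm_pos, expected_cm)

    def test_forward_burn_in_reaches_equilibrium_diversity(self):
        scen = SimScenario(name="tiny", epochs=((0, 7500),),
                           n_generations_total=75_000,
                           chromosome_length=2_000_000, rescale_Q=250,
                           sample_size=30, seed=34,
                           recomb=RecombRegions.constant(2_000_000))
        result = run_simulation(scen, burn_in="forward")
        pi = pairwise_diversity(result.haplotypes, 2_000_000)
        assert pi == pytest.approx(3e-4, rel=0.35)  # single-seed tolerance

    def test_rescaling_preserves_diversity_q5_vs_q10(self):
        """4 Ne mu is invariant, so pi at Q=5 and Q=10 must agree."""
        def mean_pi(q, seeds):
            out = []
            for seed in seeds:
                scen = SimScenario(
                    name=f"q{q}", epochs=((0, 250),), n_generations_total=2500,
                    chromosome_length=5_000_000, mutation_rate=2.5e-7,
                    rescale_Q=q, sample_size=20, seed=seed,
                    recomb=RecombRegions.constant(5_000_000))
                res = run_simulation(scen, burn_in="forward")
                out.append(pairwise_diversity(res.haplotypes, 5_000_000))
            return np.mean(out)
        pi5 = mean_pi(5, (1, 2, 3))
        pi10 = mean_pi(10, (1, 2, 3))
        assert pi5 == pytest.approx(pi10, rel=0.4)
        assert pi5 == pytest.approx(4 * 250 * 2.5e-7, rel=0.35)

    def test_site_frequency_spectrum_decreases_under_neutrality(self):
        counts = np.zeros(10, dtype=int)
        for seed in (41, 42, 43):
            pop = equilibrium_population(
                ne=100, chromosome_length=5_000_000, mutation_rate=1e-6,
                recomb=RecombRegions.constant(5_000_000, 10.0), seed=seed)
            derived = np.zeros(0)
            alleles = np.array([len(h) for h in pop.haplotypes])
            tokens = np.concatenate(pop.haplotypes)
            _, freq = np.unique(tokens, return_counts=True)
            for k in range(1, 11):
                counts[k - 1] += (freq == k).sum()
        # Watterson expectation: class k count ~ theta / k, decreasing
        assert (np.diff(counts[:3]) < 0).all()
        for k in range(1, 7):
            assert counts[k - 1] == pytest.approx(counts[0] / k, rel=0.3)

    def test_burn_in_tail_runs_forward_generations(self):
        scen = build_scenario("no_bottleneck", 1, rescale_Q=250, seed=35,
                              chromosome_length=1_000_000,
                              burn_in_tail_generations=3)
        result = run_simulation(scen)
        assert result.population.generation == 3
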