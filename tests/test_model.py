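"""Unit tests for the domain types and the four per-generation operators."""

import numpy as np
import pytest

import parfusion as pf
from parfusion.model import (
    Chrom,
    FusionScenario,
    Haplotype,
    Individual,
    SimParams,
    _fuse_copy,
    apply_fusion_mutations,
    fitness,
    initialize_population,
    make_egg,
    make_sperm,
    next_generation,
    sample_eggs,
    seed_initial_fusion,
)


class TestScenario:
    def test_four_legal_values(self):
        labels = sorted(sc.label for sc in FusionScenario)
        assert labels == ["X-PAR", "X-nonPAR", "Y-PAR", "Y-nonPAR"]

    @pytest.mark.parametrize("text,chrom,loc", [
        ("Y-nonPAR", Chrom.Y, "nonPAR"),
        ("x-par", Chrom.X, "PAR"),
        ("X-NONPAR", Chrom.X, "nonPAR"),
    ])
    def test_parsing(self, text, chrom, loc):
        sc = FusionScenario.from_string(text)
        assert sc.target_chrom is chrom
        assert sc.location.value == loc

    def test_invalid_string_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            FusionScenario.from_string("Z-PAR")


class TestSimParams:
    @pytest.mark.parametrize("kwargs,match", [
        (dict(s=1.5), "s"),
        (dict(h=-0.1), "h"),
        (dict(mu=2.0), "mu"),
        (dict(N=999), "even"),
        (dict(generations=-1), "generations"),
    ])
    def test_validation(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SimParams(scenario="Y-nonPAR", **kwargs)

    def test_scenario_coerced_from_string(self):
        p = SimParams(scenario="X-PAR")
        assert p.scenario is FusionScenario.X_PAR


class TestFitness:
    @pytest.mark.parametrize("sex,genotype,s,h,expected", [
        ("male", 0, 0.3, 0.5, 1.3),      # male 00 -> 1+s
        ("female", 1, 0.2, 0.5, 1.1),    # additive female het -> 1+hs
        ("male", 1, 0.2, 0.5, 1.1),      # additive male het -> 1+(1-h)s
        ("female", 2, 0.4, 0.0, 1.4),    # female 11 -> 1+s
        ("male", 2, 0.4, 1.0, 1.0),      # male 11 -> 1
        ("female", 1, 0.4, 0.0, 1.0),    # recessive female-benefit: het female plain
        ("male", 1, 0.4, 0.0, 1.4),      # ... while het male gets full benefit
        ("female", 1, 0.4, 1.0, 1.4),    # dominant female-benefit
        ("male", 1, 0.4, 1.0, 1.0),
    ])
    def test_table(self, sex, genotype, s, h, expected):
        assert fitness(sex, genotype, s, h) == pytest.approx(expected)

    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("genotype", [0, 1, 2])
    def test_selection_off(self, sex, genotype):
        assert fitness(sex, genotype, 0.0, 0.5) == 1.0

    def test_string_genotypes_accepted(self):
        assert fitness("male", "00", 0.3, 0.5) == pytest.approx(1.3)
        assert fitness("female", "01", 0.2, 0.5) == pytest.approx(1.1)

    @pytest.mark.parametrize("bad", [dict(s=1.2), dict(h=-0.2)])
    def test_out_of_range_parameters(self, bad):
        kwargs = dict(s=0.1, h=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            fitness("male", 0, **kwargs)

    def test_invalid_genotype(self):
        with pytest.raises(ValueError, match="genotype"):
            fitness("male", 3, 0.1, 0.5)
        with pytest.raises(ValueError, match="genotype"):
            fitness("male", "02", 0.1, 0.5)

    def test_fitness_never_below_one(self):
        for s in (0.0, 0.3, 1.0):
            for h in (0.0, 0.5, 1.0):
                for sex in ("male", "female"):
                    for g in (0, 1, 2):
                        w = fitness(sex, g, s, h)
                        assert 1.0 <= w <= 1.0 + s


class TestInitializePopulation:
    def test_structure(self, rng):
        p = SimParams(scenario="Y-nonPAR", N=4)
        pop = initialize_population(p, rng)
        assert pop.n == 4 and pop.n_females == 2
        assert not pop.fused.any()
        assert pop.generation == 0
        sexes = [i.is_female for i in pop.individuals()]
        assert sexes == [True, True, False, False]

    def test_allele_frequency_binomial(self):
        # pooled over many seeds the allele-1 frequency is 1/2 within 4 SE
        p = SimParams(scenario="Y-nonPAR", N=1000)
        total = 0
        n_seeds = 30
        for seed in range(n_seeds):
            pop = initialize_population(p, np.random.default_rng(seed))
            total += int(pop.allele.sum())
        draws = n_seeds * 2 * p.N
        se = np.sqrt(0.25 / draws)
        assert abs(total / draws - 0.5) < 4 * se

    def test_deterministic_given_seed(self):
        p = SimParams(scenario="Y-nonPAR", N=200)
        a = initialize_population(p, np.random.default_rng(5))
        b = initialize_population(p, np.random.default_rng(5))
        assert np.array_equal(a.allele, b.allele)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SimParams(scenario="Y-nonPAR", N=5)


class TestFusionMutations:
    def test_mu_zero_is_identity(self, rng, small_params):
        pop = initialize_population(small_params, rng)
        out = apply_fusion_mutations(pop, small_params.with_(mu=0.0), rng)
        assert np.array_equal(out.fused, pop.fused)
        assert np.array_equal(out.allele, pop.allele)

    def test_event_rate_matches_poisson_mean(self):
        # N=1000, mu=1/1000 -> one event per generation on average
        p = SimParams(scenario="Y-nonPAR", N=1000, mu=1e-3)
        rng = np.random.default_rng(1)
        pop = initialize_population(p, rng)
        from parfusion.model import _mutate_inplace

        n_gen = 3000
        total = sum(
            _mutate_inplace(pop.fused.copy(), pop.allele.copy(), p, rng)
            for _ in range(n_gen)
        )
        se = np.sqrt(1.0 / n_gen)  # Poisson(1) SE of the mean
        assert abs(total / n_gen - 1.0) < 4 * se

    def test_single_event_flips_one_flag_and_preserves_alleles(self, rng):
        p = SimParams(scenario="X-nonPAR", N=50, mu=0.5)
        pop = initialize_population(p, rng)
        for _ in range(50):
            out = apply_fusion_mutations(pop, p, rng)
            # fusions are only ever gained, never lost
            assert (out.fused >= pop.fused).all()
            # each individual's allele multiset is untouched
            assert np.array_equal(
                np.sort(out.allele, axis=1), np.sort(pop.allele, axis=1)
            )
            # only the target chromosome acquires fusions
            half = pop.n_females
            assert not out.fused[half:, 1].any()
            pop = out

    def test_fused_copies_are_left_alone(self, rng):
        p = SimParams(scenario="Y-nonPAR", N=10, mu=0.0)
        pop = initialize_population(p, rng)
        pop.fused[5:, 1] = True  # every Y fused
        before = pop.fused.copy()
        out = apply_fusion_mutations(pop, p.with_(mu=0.9), rng)
        assert np.array_equal(out.fused, before)


class TestSeedInitialFusion:
    @pytest.mark.parametrize("scenario", ["X-PAR", "X-nonPAR", "Y-PAR", "Y-nonPAR"])
    def test_exactly_one_fusion(self, rng, scenario):
        p = SimParams(scenario=scenario, N=100)
        pop = initialize_population(p, rng)
        out = seed_initial_fusion(pop, p, rng)
        assert out.fused.sum() == 1
        assert not pop.fused.any()  # input untouched

    def test_y_scenario_lands_on_a_male_y(self, rng):
        p = SimParams(scenario="Y-PAR", N=100)
        for _ in range(20):
            out = seed_initial_fusion(initialize_population(p, rng), p, rng)
            (row,), (col,) = np.nonzero(out.fused)
            assert row >= p.N // 2 and col == 1

    def test_allele_carried_over_from_attached_autosome(self, rng):
        # the fused haplotype's allele is one the individual already carried
        p = SimParams(scenario="X-nonPAR", N=100)
        for _ in range(20):
            pop = initialize_population(p, rng)
            out = seed_initial_fusion(pop, p, rng)
            (row,), (col,) = np.nonzero(out.fused)
            assert sorted(out.allele[row]) == sorted(pop.allele[row])

    def test_rejects_seeded_population(self, rng):
        p = SimParams(scenario="Y-nonPAR", N=100)
        pop = seed_initial_fusion(initialize_population(p, rng), p, rng)
        with pytest.raises(ValueError, match="fusion-free"):
            seed_initial_fusion(pop, p, rng)


def _empirical_egg_counts(mother, params, rng, n=20000):
    f, a = sample_eggs(mother, params, rng, n)
    return {(bool(ff), aa): int(((f == ff) & (a == aa)).sum())
            for ff in (False, True) for aa in (0, 1)}


class TestMakeEgg:
    def test_unfused_mother_symmetric(self, rng, make_hap, make_ind):
        mother = make_ind(make_hap("X", False, 0), make_hap("X", False, 1))
        p = SimParams(scenario="X-nonPAR", r=0.37)
        counts = _empirical_egg_counts(mother, p, rng)
        assert counts[(True, 0)] == counts[(True, 1)] == 0
        n = counts[(False, 0)] + counts[(False, 1)]
        assert abs(counts[(False, 1)] / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_fused_mother_r0(self, rng, make_hap, make_ind):
        # fused X carrying 1, unfused carrying 0: no crossover possible at r=0
        mother = make_ind(make_hap("X", True, 1), make_hap("X", False, 0))
        p = SimParams(scenario="X-nonPAR", r=0.0)
        counts = _empirical_egg_counts(mother, p, rng)
        assert counts[(True, 0)] == 0 and counts[(False, 1)] == 0
        n = counts[(True, 1)] + counts[(False, 0)]
        assert abs(counts[(True, 1)] / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_fused_mother_r1_forces_swap(self, rng, make_hap, make_ind):
        mother = make_ind(make_hap("X", True, 1), make_hap("X", False, 0))
        p = SimParams(scenario="X-nonPAR", r=1.0)
        counts = _empirical_egg_counts(mother, p, rng)
        assert counts[(True, 1)] == 0 and counts[(False, 0)] == 0
        assert counts[(True, 0)] > 0 and counts[(False, 1)] > 0

    def test_egg_is_always_x(self, rng, make_hap, make_ind):
        mother = make_ind(make_hap("X", True, 1), make_hap("X", False, 0))
        p = SimParams(scenario="X-PAR", r=0.3)
        for _ in range(20):
            assert make_egg(mother, p, rng).chrom is Chrom.X

    def test_male_rejected(self, rng, make_hap, make_ind):
        father = make_ind(make_hap("X", False, 0), make_hap("Y", False, 1))
        with pytest.raises(ValueError, match="female"):
            make_egg(father, SimParams(scenario="Y-nonPAR"), rng)


class TestMakeSperm:
    def test_par_fusion_swaps_to_other_chromosome(self, rng, make_hap, make_ind):
        # X-PAR fusion carrying allele 1: the obligate PAR crossover moves it
        # to the Y, so Y-sperm are always fused(1), X-sperm always unfused(0)
        father = make_ind(make_hap("X", True, 1), make_hap("Y", False, 0))
        p = SimParams(scenario="X-PAR", r=0.0)
        for _ in range(30):
            y = make_sperm(father, Chrom.Y, p, rng)
            assert (y.chrom, y.fused, y.sal_allele) == (Chrom.Y, True, 1)
            x = make_sperm(father, Chrom.X, p, rng)
            assert (x.chrom, x.fused, x.sal_allele) == (Chrom.X, False, 0)

    def test_nonpar_fusion_is_stable(self, rng, make_hap, make_ind):
        father = make_ind(make_hap("X", False, 0), make_hap("Y", True, 1))
        p = SimParams(scenario="Y-nonPAR", r=0.0)
        for _ in range(30):
            y = make_sperm(father, Chrom.Y, p, rng)
            assert (y.fused, y.sal_allele) == (True, 1)

    def test_both_fused_par_exchanges_attachments(self, rng, make_hap, make_ind):
        father = make_ind(make_hap("X", True, 1), make_hap("Y", True, 0))
        p = SimParams(scenario="Y-PAR", r=0.0)
        y = make_sperm(father, Chrom.Y, p, rng)
        x = make_sperm(father, Chrom.X, p, rng)
        assert (y.fused, y.sal_allele) == (True, 1)
        assert (x.fused, x.sal_allele) == (True, 0)

    def test_female_rejected(self, rng, make_hap, make_ind):
        mother = make_ind(make_hap("X", False, 0), make_hap("X", False, 1))
        with pytest.raises(ValueError, match="male"):
            make_sperm(mother, Chrom.Y, SimParams(scenario="Y-nonPAR"), rng)


class TestNextGeneration:
    def test_conservation(self, rng, small_params):
        pop = initialize_population(small_params, rng)
        out = next_generation(pop, small_params, rng)
        assert out.n == pop.n
        assert out.generation == 1
        assert sum(i.is_female for i in out.individuals()) == pop.n_females

    def test_paternity_proportional_to_fitness(self):
        # males split between genotype 00 (fitness 1.3) and 11 (fitness 1.0)
        # at s=0.3, h=0.5; sons' paternal allele identifies the father class
        p = SimParams(scenario="Y-nonPAR", s=0.3, h=0.5, r=0.1, mu=0.0, N=400)
        rng = np.random.default_rng(42)
        pop = initialize_population(p, rng)
        half = p.N // 2
        pop.allele[half:half + half // 2] = 0
        pop.allele[half + half // 2:] = 1
        count_0 = 0
        total = 0
        for _ in range(60):
            out = next_generation(pop, p, rng)
            pat = out.allele[half:, 1]  # sons' Y-side allele
            count_0 += int((pat == 0).sum())
            total += pat.size
        expected = 1.3 / 2.3
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(count_0 / total - expected) < 4 * se

    def test_neutral_sampling_is_uniform_over_genotypes(self):
        p = SimParams(scenario="Y-nonPAR", s=0.0, h=0.5, r=0.1, mu=0.0, N=400)
        rng = np.random.default_rng(43)
        pop = initialize_population(p, rng)
        half = p.N // 2
        pop.allele[half:half + half // 2] = 0
        pop.allele[half + half // 2:] = 1
        count_0 = 0
        total = 0
        for _ in range(60):
            out = next_generation(pop, p, rng)
            pat = out.allele[half:, 1]
            count_0 += int((pat == 0).sum())
            total += pat.size
        se = np.sqrt(0.25 / total)
        assert abs(count_0 / total - 0.5) < 4 * se


class TestHaplotypeIndividual:
    def test_maternal_must_be_x(self, make_hap):
        with pytest.raises(ValueError, match="X"):
            Individual(make_hap("Y", False, 0), make_hap("X", False, 0))

    def test_sex_from_paternal_chromosome(self, make_hap, make_ind):
        assert make_ind(make_hap(), make_hap("X")).is_female
        assert not make_ind(make_hap(), make_hap("Y")).is_female

    def test_invalid_allele(self):
        with pytest.raises(ValueError, match="sal_allele"):
            Haplotype(Chrom.X, False, 2)
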