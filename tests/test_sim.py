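import numpy as np
import pytest

from amadjust import (
    ArchitectureSpec,
    PopulationState,
    SortingSpec,
    breed,
    compute_traits,
    draw_effects,
    evolve,
    init_founders,
    match_mates,
)
from conftest import rg_of


class TestFounders:
    def test_binomial_moments_and_support(self):
        arch = ArchitectureSpec(n_individuals=4_000, n_snps=400, n_chrom=20)
        pop = init_founders(arch, seed=1)
        g = pop.genotypes
        assert set(np.unique(g)) <= {0, 1, 2}
        # Binomial(2, 0.5): mean 1, variance 0.5; per-SNP sampling SE ~ 0.011
        assert abs(g.mean() - 1.0) < 0.01
        assert abs(g.var() - 0.5) < 0.01
        assert np.all(np.abs(g.mean(axis=0) - 1.0) < 0.06)
        assert pop.generation == 1
        assert pop.sex.sum() == arch.n_individuals // 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_individuals": 1001},
            {"n_snps": 201, "n_chrom": 20},
            {"allele_freq": 0.0},
            {"allele_freq": 1.2},
        ],
    )
    def test_invalid_architecture_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArchitectureSpec(**{"n_individuals": 1000, "n_snps": 200, "n_chrom": 20, **kwargs})

    def test_cross_chromosome_correlations_at_null_level(self):
        # Independent loci: E[r^2] between any two SNPs is ~ 1/(n-1).  The
        # mean squared cross-chromosome correlation must sit at that noise
        # floor (oracle: the closed-form null expectation).
        arch = ArchitectureSpec(n_individuals=400, n_snps=100, n_chrom=10)
        pop = init_founders(arch, seed=3)
        r = np.corrcoef(pop.genotypes.T)
        cross = pop.chrom_of_snp[:, None] != pop.chrom_of_snp[None, :]
        mean_r2 = (r[cross] ** 2).mean()
        null = 1.0 / (arch.n_individuals - 1)
        assert 0.6 * null < mean_r2 < 1.6 * null


class TestEffects:
    @pytest.mark.parametrize("target", [0.0, 0.5])
    def test_full_pleiotropy_hits_target_correlation(self, target):
        arch = ArchitectureSpec(pleiotropy_mode="full", effect_correlation=target)
        arch = draw_effects(arch, seed=5)
        got = np.corrcoef(arch.beta_z, arch.beta_y)[0, 1]
        assert abs(got - target) < 0.06  # 2000 SNPs: SE of r ~ 0.02

    def test_no_pleiotropy_means_disjoint_support(self):
        arch = draw_effects(ArchitectureSpec(pleiotropy_mode="none"), seed=6)
        active_both = (arch.beta_z != 0) & (arch.beta_y != 0)
        assert not active_both.any()
        assert abs(np.corrcoef(arch.beta_z, arch.beta_y)[0, 1]) < 0.06

    def test_partial_pleiotropy_splits_snps(self):
        arch = draw_effects(
            ArchitectureSpec(pleiotropy_mode="partial", partial_fraction=0.5), seed=7
        )
        both = (arch.beta_z != 0) & (arch.beta_y != 0)
        z_only = (arch.beta_z != 0) & (arch.beta_y == 0)
        y_only = (arch.beta_z == 0) & (arch.beta_y != 0)
        m = arch.n_snps
        assert both.sum() == m // 2
        assert z_only.sum() == m // 4
        assert y_only.sum() == m // 4
        r_pleio = np.corrcoef(arch.beta_z[both], arch.beta_y[both])[0, 1]
        assert abs(r_pleio - 0.5) < 0.09

    def test_effect_validation(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(effect_correlation=1.5)
        with pytest.raises(ValueError):
            ArchitectureSpec(partial_fraction=-0.1)


class TestTraits:
    def test_perfect_heritability_identities(self, small_world):
        _, _, traits = small_world
        assert np.array_equal(traits.z, traits.g_z)
        assert np.all(traits.e_z == 0) and np.all(traits.e_y == 0)
        # chromosome-partial factors partition the genome-wide factor exactly
        assert np.array_equal(traits.g_chrom_z.sum(axis=1), traits.g_z)
        assert np.array_equal(traits.g_chrom_y.sum(axis=1), traits.g_y)

    def test_subunit_heritability_scales_noise(self):
        arch = draw_effects(
            ArchitectureSpec(n_individuals=4_000, n_snps=200, n_chrom=10, h2_z=0.5), seed=8
        )
        pop = init_founders(arch, seed=9)
        traits = compute_traits(pop, arch, seed=10)
        ratio = traits.g_z.var() / traits.z.var()
        assert abs(ratio - 0.5) < 0.04
        with pytest.raises(ValueError):
            compute_traits(pop, arch)  # h2 < 1 without a seed

    def test_missing_effects_rejected(self):
        arch = ArchitectureSpec(n_individuals=200, n_snps=20, n_chrom=2)
        pop = init_founders(arch, seed=1)
        with pytest.raises(ValueError):
            compute_traits(pop, arch)


class TestMating:
    def _world(self, n=10_000, seed=20):
        arch = draw_effects(ArchitectureSpec(n_individuals=n), seed=seed)
        pop = init_founders(arch, seed=seed + 1)
        return arch, pop, compute_traits(pop, arch)

    def test_random_pairing_uncorrelated(self):
        _, pop, traits = self._world(n=4_000)
        pairs = match_mates(pop, traits, SortingSpec("random"), seed=30)
        r = np.corrcoef(traits.z[pairs[:, 0]], traits.z[pairs[:, 1]])[0, 1]
        assert abs(r) < 0.08  # ~3.5 / sqrt(2000 pairs)

    def test_rank_matching_gives_near_perfect_mate_correlation(self):
        # order statistics of two iid samples of 5000 correlate > 0.99
        _, pop, traits = self._world(n=10_000)
        pairs = match_mates(pop, traits, SortingSpec("treatment"), seed=31)
        r = np.corrcoef(traits.z[pairs[:, 0]], traits.z[pairs[:, 1]])[0, 1]
        assert r > 0.99

    def test_cross_trait_matching(self):
        arch, pop, traits = self._world(n=10_000)
        pairs = match_mates(pop, traits, SortingSpec("cross_trait"), seed=32)
        r_zy = np.corrcoef(traits.z[pairs[:, 0]], traits.y[pairs[:, 1]])[0, 1]
        r_zz = np.corrcoef(traits.z[pairs[:, 0]], traits.z[pairs[:, 1]])[0, 1]
        assert r_zy > 0.99
        # same-trait mate correlation is diluted by the genetic correlation
        assert abs(r_zz - arch.effect_correlation * r_zy) < 0.1

    def test_multi_trait_matching_uses_both_traits(self):
        _, pop, traits = self._world(n=4_000)
        pairs = match_mates(pop, traits, SortingSpec("multi_trait"), seed=33)
        s = lambda v: (v - v.mean()) / v.std()
        score = s(traits.z) + s(traits.y)
        r = np.corrcoef(score[pairs[:, 0]], score[pairs[:, 1]])[0, 1]
        assert r > 0.99

    def test_match_noise_degrades_sorting(self):
        _, pop, traits = self._world(n=4_000)
        exact = match_mates(pop, traits, SortingSpec("treatment"), seed=34)
        noisy = match_mates(pop, traits, SortingSpec("treatment", match_noise=1.0), seed=34)
        r_exact = np.corrcoef(traits.z[exact[:, 0]], traits.z[exact[:, 1]])[0, 1]
        r_noisy = np.corrcoef(traits.z[noisy[:, 0]], traits.z[noisy[:, 1]])[0, 1]
        assert r_noisy < r_exact
        assert 0.2 < r_noisy < 0.8  # noise sd = score sd -> r ~ 0.5

    def test_unequal_sex_counts_rejected(self, small_world):
        arch, pop, traits = small_world
        lopsided = PopulationState(
            genotypes=pop.genotypes,
            chrom_of_snp=pop.chrom_of_snp,
            sex=np.ones(pop.n_individuals, bool),
            generation=1,
        )
        with pytest.raises(ValueError, match="unequal sex"):
            match_mates(lopsided, traits, SortingSpec("treatment"), seed=1)

    def test_sorting_spec_validation(self):
        with pytest.raises(ValueError):
            SortingSpec("bogus")
        with pytest.raises(ValueError):
            SortingSpec("multi_trait", female_weights=(0.0, 0.0))
        with pytest.raises(ValueError):
            SortingSpec("treatment", match_noise=-1.0)


class TestBreeding:
    def test_forced_mendelian_outcome(self):
        # a 0x2 cross can only produce heterozygotes
        geno = np.array([[0, 2], [2, 0]], dtype=np.int8)
        pop = PopulationState(
            genotypes=geno, chrom_of_snp=[1, 2], sex=[True, False], generation=1
        )
        child = breed(np.array([[0, 1]]), pop, seed=40)
        assert np.all(child.genotypes == 1)
        assert child.n_individuals == 2  # two offspring per pair
        assert child.generation == 2

    def test_population_size_and_frequency_conserved(self):
        arch = draw_effects(ArchitectureSpec(n_individuals=1_000, n_snps=100, n_chrom=10), seed=41)
        pop = init_founders(arch, seed=42)
        traits = compute_traits(pop, arch)
        diffs = []
        for rep in range(20):
            pairs = match_mates(pop, traits, SortingSpec("random"), seed=100 + rep)
            child = breed(pairs, pop, seed=200 + rep)
            assert child.n_individuals == pop.n_individuals
            child.validate_genotypes()
            diffs.append(child.genotypes.mean() - pop.genotypes.mean())
        # Mendelian transmission conserves allele frequency in expectation
        assert abs(np.mean(diffs)) < 0.005

    def test_incomplete_pairing_rejected(self, small_world):
        _, pop, _ = small_world
        with pytest.raises(ValueError, match="cover"):
            breed(np.array([[0, 1], [0, 2]]), pop, seed=1)

    def test_breeding_is_deterministic(self, small_world):
        _, pop, traits = small_world
        pairs = match_mates(pop, traits, SortingSpec("treatment"), seed=50)
        a = breed(pairs, pop, seed=51)
        b = breed(pairs, pop, seed=51)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.sex, b.sex)


class TestEvolve:
    def test_generation_labels_and_count(self):
        arch = ArchitectureSpec(n_individuals=400, n_snps=100, n_chrom=10)
        res = evolve(arch, SortingSpec("random"), n_generations=3, seed=60)
        assert res.n_generations == 3
        assert [g.population.generation for g in res] == [1, 2, 3]
        with pytest.raises(ValueError):
            evolve(arch, SortingSpec("random"), n_generations=0, seed=60)

    def test_random_mating_keeps_genetic_variance_stable(self):
        arch = ArchitectureSpec(n_individuals=2_000, n_snps=200, n_chrom=10)
        ratios = []
        for rep in range(5):
            res = evolve(arch, SortingSpec("random"), n_generations=4, seed=70 + rep)
            ratios.append(res[3].traits.g_z.var() / res[0].traits.g_z.var())
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_sorting_inflates_genetic_variance(self):
        arch = ArchitectureSpec(n_individuals=2_000, n_snps=200, n_chrom=10)
        gains = []
        for rep in range(3):
            res = evolve(arch, SortingSpec("treatment"), n_generations=4, seed=80 + rep)
            v = [g.traits.g_z.var() for g in res]
            gains.append(v[3] / v[0])
        # one generation of perfect sorting on a perfectly heritable trait
        # already adds ~50% genetic variance, compounding thereafter
        assert np.mean(gains) > 1.5

    def test_same_seed_bit_identical(self):
        arch = ArchitectureSpec(n_individuals=400, n_snps=100, n_chrom=10)
        a = evolve(arch, SortingSpec("outcome"), n_generations=3, seed=90)
        b = evolve(arch, SortingSpec("outcome"), n_generations=3, seed=90)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.population.genotypes, gb.population.genotypes)
            assert np.array_equal(ga.traits.z, gb.traits.z)

    def test_random_sorting_keeps_rg_stable(self):
        arch = ArchitectureSpec(n_individuals=2_000, n_snps=200, n_chrom=10)
        drifts = []
        for rep in range(5):
            res = evolve(arch, SortingSpec("random"), n_generations=4, seed=95 + rep)
            drifts.append(rg_of(res[3].traits) - rg_of(res[0].traits))
        assert abs(np.mean(drifts)) < 0.04
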