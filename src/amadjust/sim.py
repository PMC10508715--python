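"""Forward-time diploid simulation of assortative mating (AM).

The simulator produces multi-generation populations with a known panmictic
(randomly mating) truth, which is the reference state for every adjustment in
this package.  The model is deliberately stylized:

* founders carry ``Binomial(2, p)`` genotypes at ``M`` biallelic SNPs arranged
  in ``C`` equal chromosome blocks (chromosome membership is the only genomic
  structure the method uses);
* all loci segregate independently ("free recombination"), so any genotype
  correlation between loci in later generations is AM-induced gametic-phase
  disequilibrium, not linkage;
* two traits, a "treatment" Z and an "outcome" Y, are linear in allele counts,
  perfectly heritable by default, and optionally connected by a causal effect
  ``Y = gamma * Z + direct genetics + noise``;
* each generation, the population is split at random into equal numbers of
  females and males, mates are matched by the rank of a sorting score, and each
  pair leaves exactly two offspring, keeping the population size constant.

Trait values are never re-standardized across generations: the inflation of
genetic variance and covariance is the object of study.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArchitectureSpec",
    "SortingSpec",
    "PopulationState",
    "TraitPanel",
    "Generation",
    "SimulationResult",
    "init_founders",
    "draw_effects",
    "compute_traits",
    "match_mates",
    "breed",
    "evolve",
]

_PLEIOTROPY_MODES = ("full", "partial", "none")
_MECHANISMS = ("random", "treatment", "outcome", "cross_trait", "multi_trait")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of the two simulated traits.

    Parameters
    ----------
    n_individuals
        Population size (constant across generations; must be even so the
        population can be split into mating pairs).
    n_snps, n_chrom
        Number of SNPs and of equal-sized chromosome blocks; ``n_snps`` must be
        divisible by ``n_chrom``.
    allele_freq
        Founder allele frequency, shared by every SNP.
    pleiotropy_mode
        ``"full"``: every SNP affects both traits, effects drawn jointly with
        correlation ``effect_correlation``.  ``"none"``: disjoint halves of the
        SNPs affect each trait.  ``"partial"``: a fraction
        ``partial_fraction`` of SNPs is pleiotropic (correlated effects), the
        remainder is split evenly into trait-specific SNPs.
    effect_correlation
        Target correlation of the per-SNP effect pairs among pleiotropic SNPs.
    h2_z, h2_y
        Panmictic heritabilities in (0, 1]; 1 means no environmental noise.
    causal_effect
        Causal effect ``gamma`` of Z on Y.  The total projection effect of SNP
        j on Y is then ``gamma * beta_z[j] + beta_y[j]`` where ``beta_y`` holds
        the direct effects.
    beta_z, beta_y
        Per-SNP effect vectors (direct effects); filled by
        :func:`draw_effects` when ``None``.
    """

    n_individuals: int = 10_000
    n_snps: int = 2_000
    n_chrom: int = 20
    allele_freq: float = 0.5
    pleiotropy_mode: str = "full"
    effect_correlation: float = 0.5
    partial_fraction: float = 0.5
    h2_z: float = 1.0
    h2_y: float = 1.0
    causal_effect: float = 0.0
    beta_z: np.ndarray | None = None
    beta_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_individuals % 2:
            raise ValueError(
                f"n_individuals must be positive and even, got {self.n_individuals}"
            )
        if self.n_chrom < 1 or self.n_snps % self.n_chrom:
            raise ValueError(
                f"n_snps ({self.n_snps}) must be divisible by n_chrom ({self.n_chrom})"
            )
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"allele_freq must lie in (0, 1), got {self.allele_freq}")
        if self.pleiotropy_mode not in _PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if abs(self.effect_correlation) > 1.0:
            raise ValueError("effect_correlation must lie in [-1, 1]")
        if not 0.0 <= self.partial_fraction <= 1.0:
            raise ValueError("partial_fraction must lie in [0, 1]")
        for name, h2 in (("h2_z", self.h2_z), ("h2_y", self.h2_y)):
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {h2}")
        for name, b in (("beta_z", self.beta_z), ("beta_y", self.beta_y)):
            if b is not None and len(b) != self.n_snps:
                raise ValueError(f"{name} must have length n_snps={self.n_snps}")
        if (
            self.pleiotropy_mode == "none"
            and self.beta_z is not None
            and self.beta_y is not None
            and np.any((np.asarray(self.beta_z) != 0) & (np.asarray(self.beta_y) != 0))
        ):
            raise ValueError("pleiotropy_mode='none' forbids SNPs active for both traits")

    @property
    def chrom_of_snp(self) -> np.ndarray:
        """Chromosome label (1..C) of every SNP, in equal contiguous blocks."""
        return np.repeat(np.arange(1, self.n_chrom + 1), self.n_snps // self.n_chrom)

    @property
    def beta_y_total(self) -> np.ndarray:
        """Total projection effects on Y: causal path through Z plus direct."""
        if self.beta_z is None or self.beta_y is None:
            raise ValueError("effects have not been drawn; call draw_effects first")
        return self.causal_effect * np.asarray(self.beta_z) + np.asarray(self.beta_y)

    def with_effects(self, beta_z: np.ndarray, beta_y: np.ndarray) -> "ArchitectureSpec":
        return replace(self, beta_z=np.asarray(beta_z, float), beta_y=np.asarray(beta_y, float))


@dataclass(frozen=True)
class SortingSpec:
    """How mates are matched.

    ``mechanism``:

    * ``"random"`` – uniform random pairing (panmixia); all other fields are
      ignored.
    * ``"treatment"`` – both sexes ranked on Z, matched rank-to-rank.
    * ``"outcome"`` – both sexes ranked on Y.
    * ``"cross_trait"`` – females ranked on Z, males on Y.
    * ``"multi_trait"`` – each sex ranked on a weighted sum of its
      within-generation standardized Z and Y scores.

    ``match_noise`` > 0 perturbs the sorting scores with independent Gaussian
    noise of that many score standard deviations before ranking, allowing
    sub-perfect mate correlations; the default 0 is exact rank matching.
    """

    mechanism: str = "random"
    female_weights: tuple[float, float] = (1.0, 1.0)
    male_weights: tuple[float, float] = (1.0, 1.0)
    match_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"unknown mating mechanism {self.mechanism!r}")
        if self.match_noise < 0:
            raise ValueError("match_noise must be >= 0")
        if self.mechanism == "multi_trait":
            for name, w in (("female_weights", self.female_weights), ("male_weights", self.male_weights)):
                if not any(x != 0 for x in w):
                    raise ValueError(f"multi_trait requires a nonzero weight in {name}")


@dataclass
class PopulationState:
    """Genotypes and bookkeeping for one generation.

    ``genotypes`` is an individuals x SNPs matrix of reference-allele counts
    (0, 1 or 2).  ``sex`` is a boolean vector, ``True`` for females.
    """

    genotypes: np.ndarray
    chrom_of_snp: np.ndarray
    sex: np.ndarray
    generation: int
    seed_record: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.chrom_of_snp = np.asarray(self.chrom_of_snp)
        self.sex = np.asarray(self.sex, bool)
        n, m = self.genotypes.shape
        if n % 2:
            raise ValueError("number of individuals must be even")
        if len(self.chrom_of_snp) != m:
            raise ValueError("chrom_of_snp length must equal the SNP count")
        if len(self.sex) != n:
            raise ValueError("sex length must equal the individual count")
        if self.generation < 1:
            raise ValueError("generation index starts at 1")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate_genotypes(self) -> None:
        g = self.genotypes
        if g.min() < 0 or g.max() > 2:
            raise ValueError("genotype entries must be 0, 1 or 2")


@dataclass
class TraitPanel:
    """Trait values and their genetic decomposition for one generation.

    ``z = g_z + e_z`` and ``y = g_y + e_y`` hold element-wise, and the
    chromosome-partial genetic factors sum exactly to the genome-wide factors:
    ``g_chrom_z.sum(axis=1) == g_z``.
    """

    z: np.ndarray
    y: np.ndarray
    g_z: np.ndarray
    g_y: np.ndarray
    e_z: np.ndarray
    e_y: np.ndarray
    g_chrom_z: np.ndarray
    g_chrom_y: np.ndarray
    noise_sd: tuple[float, float] = (0.0, 0.0)


def _random_bits(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Fair coin flips as a uint8 0/1 array, drawn bit-packed for speed."""
    n = int(np.prod(shape))
    packed = rng.integers(0, 256, size=(n + 7) // 8, dtype=np.uint8)
    return np.unpackbits(packed)[:n].reshape(shape)


def init_founders(arch: ArchitectureSpec, seed: int) -> PopulationState:
    """Draw a panmictic founder population.

    Every genotype is an independent ``Binomial(2, p)`` draw, so all loci are
    in linkage equilibrium in expectation; sexes are a random half-split.
    """
    rng = np.random.default_rng(seed)
    n, m = arch.n_individuals, arch.n_snps
    if arch.allele_freq == 0.5:
        # Binomial(2, 1/2) is the sum of two fair coin flips
        genotypes = (_random_bits(rng, (n, m)) + _random_bits(rng, (n, m))).astype(np.int8)
    else:
        genotypes = rng.binomial(2, arch.allele_freq, size=(n, m)).astype(np.int8)
    sex = np.zeros(n, bool)
    sex[rng.permutation(n)[: n // 2]] = True
    return PopulationState(
        genotypes=genotypes,
        chrom_of_snp=arch.chrom_of_snp,
        sex=sex,
        generation=1,
        seed_record=(int(seed),),
    )


def draw_effects(arch: ArchitectureSpec, seed: int) -> ArchitectureSpec:
    """Fill the per-SNP effect vectors according to the pleiotropy mode.

    Active effects are standard normal; pleiotropic pairs are drawn from a
    bivariate normal with the target effect correlation.
    """
    rng = np.random.default_rng(seed)
    m = arch.n_snps
    r = arch.effect_correlation
    cov = np.array([[1.0, r], [r, 1.0]])

    if arch.pleiotropy_mode == "full":
        eff = rng.multivariate_normal([0.0, 0.0], cov, size=m)
        beta_z, beta_y = eff[:, 0], eff[:, 1]
    elif arch.pleiotropy_mode == "none":
        perm = rng.permutation(m)
        z_only, y_only = perm[: m // 2], perm[m // 2 :]
        beta_z = np.zeros(m)
        beta_y = np.zeros(m)
        beta_z[z_only] = rng.standard_normal(len(z_only))
        beta_y[y_only] = rng.standard_normal(len(y_only))
    else:  # partial
        n_pleio = int(round(arch.partial_fraction * m))
        perm = rng.permutation(m)
        pleio = perm[:n_pleio]
        rest = perm[n_pleio:]
        z_only, y_only = rest[: len(rest) // 2], rest[len(rest) // 2 :]
        beta_z = np.zeros(m)
        beta_y = np.zeros(m)
        if n_pleio:
            eff = rng.multivariate_normal([0.0, 0.0], cov, size=n_pleio)
            beta_z[pleio], beta_y[pleio] = eff[:, 0], eff[:, 1]
        beta_z[z_only] = rng.standard_normal(len(z_only))
        beta_y[y_only] = rng.standard_normal(len(y_only))

    return arch.with_effects(beta_z, beta_y)


def _block_weight_matrix(chrom_of_snp: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """SNPs x chromosomes matrix placing each weight in its chromosome column,
    so chromosome-partial factors are a single matmul ``x @ W``."""
    chroms = np.unique(chrom_of_snp)
    w = np.zeros((len(beta), len(chroms)))
    col = np.searchsorted(chroms, chrom_of_snp)
    w[np.arange(len(beta)), col] = beta
    return w


def _chrom_partial_factors(
    genotypes: np.ndarray, chrom_of_snp: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Individuals x chromosomes matrix of block-restricted genetic factors."""
    x = genotypes.astype(np.float64, copy=False)
    return x @ _block_weight_matrix(chrom_of_snp, beta)


def compute_traits(
    pop: PopulationState,
    arch: ArchitectureSpec,
    seed: int | None = None,
    noise_sd: tuple[float, float] | None = None,
) -> TraitPanel:
    """Build trait values and their genetic decomposition.

    With the default perfect heritability the traits equal their genetic
    factors exactly.  With ``h2 < 1``, independent Gaussian noise is added; its
    standard deviation is fixed so that ``Var(g)/Var(trait) = h2`` in the
    generation where it is first computed (pass the resulting ``noise_sd`` back
    in for later generations so the environmental variance stays constant).
    """
    if arch.beta_z is None or arch.beta_y is None:
        raise ValueError("effects have not been drawn; call draw_effects first")
    beta_z = np.asarray(arch.beta_z, float)
    beta_yt = np.asarray(arch.beta_y_total, float)

    x = pop.genotypes.astype(np.float64, copy=False)  # one float copy for both traits
    g_chrom_z = x @ _block_weight_matrix(pop.chrom_of_snp, beta_z)
    g_chrom_y = x @ _block_weight_matrix(pop.chrom_of_snp, beta_yt)
    # summing the block factors keeps the partition identity exact in floats
    g_z = g_chrom_z.sum(axis=1)
    g_y = g_chrom_y.sum(axis=1)

    if noise_sd is None:
        sd_z = (
            0.0
            if arch.h2_z == 1.0
            else float(np.sqrt(g_z.var() * (1.0 - arch.h2_z) / arch.h2_z))
        )
        sd_y = (
            0.0
            if arch.h2_y == 1.0
            else float(np.sqrt((g_y - arch.causal_effect * g_z).var() * (1.0 - arch.h2_y) / arch.h2_y))
        )
        noise_sd = (sd_z, sd_y)
    sd_z, sd_y = noise_sd

    if sd_z > 0 or sd_y > 0:
        if seed is None:
            raise ValueError("a seed is required when h2 < 1")
        rng = np.random.default_rng(seed)
        e_z = rng.normal(0.0, sd_z, pop.n_individuals) if sd_z > 0 else np.zeros(pop.n_individuals)
        e_y_direct = rng.normal(0.0, sd_y, pop.n_individuals) if sd_y > 0 else np.zeros(pop.n_individuals)
    else:
        e_z = np.zeros(pop.n_individuals)
        e_y_direct = np.zeros(pop.n_individuals)

    z = g_z + e_z
    # Y = gamma*Z + direct genetics + direct noise; the genetic factor of Y is
    # gamma*g_z + g_y_direct (already folded into beta_y_total), so gamma*e_z
    # lands in Y's environmental residual.
    e_y = arch.causal_effect * e_z + e_y_direct
    y = g_y + e_y
    return TraitPanel(
        z=z,
        y=y,
        g_z=g_z,
        g_y=g_y,
        e_z=e_z,
        e_y=e_y,
        g_chrom_z=g_chrom_z,
        g_chrom_y=g_chrom_y,
        noise_sd=(sd_z, sd_y),
    )


def _rank_order(score: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending order of ``score`` with ties broken by a random permutation."""
    perm = rng.permutation(len(score))
    return perm[np.argsort(score[perm], kind="stable")]


def _sorting_scores(
    traits: TraitPanel, sorting: SortingSpec, f_idx: np.ndarray, m_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if sorting.mechanism == "treatment":
        return traits.z[f_idx], traits.z[m_idx]
    if sorting.mechanism == "outcome":
        return traits.y[f_idx], traits.y[m_idx]
    if sorting.mechanism == "cross_trait":
        return traits.z[f_idx], traits.y[m_idx]
    # multi_trait: weighted sum of within-generation standardized traits
    z_std = (traits.z - traits.z.mean()) / traits.z.std()
    y_std = (traits.y - traits.y.mean()) / traits.y.std()
    wf, wm = sorting.female_weights, sorting.male_weights
    return (
        wf[0] * z_std[f_idx] + wf[1] * y_std[f_idx],
        wm[0] * z_std[m_idx] + wm[1] * y_std[m_idx],
    )


def match_mates(
    pop: PopulationState,
    traits: TraitPanel,
    sorting: SortingSpec,
    seed: int,
) -> np.ndarray:
    """Pair every female with a male; returns an (n/2, 2) array of
    (mother index, father index) rows.

    Non-random mechanisms rank each sex on its sorting score and match
    rank-to-rank, so with ``match_noise=0`` the highest-scoring male marries
    the highest-scoring female.
    """
    rng = np.random.default_rng(seed)
    f_idx = np.flatnonzero(pop.sex)
    m_idx = np.flatnonzero(~pop.sex)
    if len(f_idx) != len(m_idx):
        raise ValueError(f"unequal sex counts: {len(f_idx)} females, {len(m_idx)} males")

    if sorting.mechanism == "random":
        mothers = f_idx[rng.permutation(len(f_idx))]
        fathers = m_idx[rng.permutation(len(m_idx))]
        return np.column_stack([mothers, fathers])

    fs, ms = _sorting_scores(traits, sorting, f_idx, m_idx)
    if sorting.match_noise > 0:
        fs = fs + rng.normal(0.0, sorting.match_noise * fs.std(), len(fs))
        ms = ms + rng.normal(0.0, sorting.match_noise * ms.std(), len(ms))
    mothers = f_idx[_rank_order(np.asarray(fs, float), rng)]
    fathers = m_idx[_rank_order(np.asarray(ms, float), rng)]
    return np.column_stack([mothers, fathers])


def breed(pairs: np.ndarray, pop: PopulationState, seed: int) -> PopulationState:
    """Produce the next generation: two offspring per pair, free recombination.

    At every SNP each offspring receives one allele drawn uniformly from the
    mother's two and one from the father's two, independently across SNPs, so
    the transmitted count from a parent with genotype ``x`` is
    ``Bernoulli(x/2)``.
    """
    pairs = np.asarray(pairs)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n_pairs, 2) index array")
    used = np.sort(pairs.ravel())
    if len(used) != pop.n_individuals or np.any(used != np.arange(pop.n_individuals)):
        raise ValueError("pairs must cover every individual exactly once")

    rng = np.random.default_rng(seed)
    xm = pop.genotypes[pairs[:, 0]]
    xp = pop.genotypes[pairs[:, 1]]

    def transmit(x: np.ndarray) -> np.ndarray:
        # Bernoulli(x/2): homozygotes transmit deterministically, heterozygotes
        # flip a fair coin per SNP
        return (x == 2) + ((x == 1) & (_random_bits(rng, x.shape) == 1))

    kids = [(transmit(xm).astype(np.int8) + transmit(xp)).astype(np.int8) for _ in range(2)]
    genotypes = np.vstack(kids)
    n = genotypes.shape[0]
    sex = np.zeros(n, bool)
    sex[rng.permutation(n)[: n // 2]] = True
    return PopulationState(
        genotypes=genotypes,
        chrom_of_snp=pop.chrom_of_snp,
        sex=sex,
        generation=pop.generation + 1,
        seed_record=pop.seed_record + (int(seed),),
    )


@dataclass
class Generation:
    population: PopulationState
    traits: TraitPanel


@dataclass
class SimulationResult:
    generations: list[Generation]
    arch: ArchitectureSpec
    sorting: SortingSpec

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    def __getitem__(self, i: int) -> Generation:
        return self.generations[i]

    def __iter__(self):
        return iter(self.generations)


def evolve(
    arch: ArchitectureSpec,
    sorting: SortingSpec,
    n_generations: int = 4,
    seed: int = 0,
) -> SimulationResult:
    """Run the full multi-generation experiment.

    Generation 1 is a panmictic founder population; each later generation is
    produced by mate matching under ``sorting`` followed by breeding, using the
    same effect sizes throughout.  The default 4 generations give one random
    mating snapshot and three with compounding sorting.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(2**31))

    if arch.beta_z is None or arch.beta_y is None:
        arch = draw_effects(arch, sub())
    pop = init_founders(arch, sub())
    traits = compute_traits(pop, arch, seed=sub())
    noise_sd = traits.noise_sd
    generations = [Generation(pop, traits)]
    for _ in range(n_generations - 1):
        pairs = match_mates(pop, traits, sorting, sub())
        pop = breed(pairs, pop, sub())
        traits = compute_traits(pop, arch, seed=sub(), noise_sd=noise_sd)
        generations.append(Generation(pop, traits))
    return SimulationResult(generations, arch, sorting)
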