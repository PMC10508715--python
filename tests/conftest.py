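import numpy as np
import pytest

from amadjust import (
    ArchitectureSpec,
    compute_traits,
    draw_effects,
    init_founders,
)


def lean_betas(y: np.ndarray, pop) -> np.ndarray:
    """Per-SNP OLS slopes only (fast path for replicate-averaged scans).

    Centered-y algebra: sum x*(y-ybar) equals the fully centered cross
    product, so the genotype matrix is never copied or centered.
    """
    x = pop.genotypes
    n = x.shape[0]
    n1 = (x == 1).sum(0)
    n2 = (x == 2).sum(0)
    xm = (n1 + 2.0 * n2) / n
    sxx = (n1 + 4.0 * n2) - n * xm**2
    yc = y - y.mean()
    return (yc @ x.astype(np.float32, copy=False)) / sxx


def rg_of(traits) -> float:
    """Score correlation (the genetic correlation) of a trait panel."""
    return float(np.corrcoef(traits.g_z, traits.g_y)[0, 1])


@pytest.fixture(scope="session")
def small_arch() -> ArchitectureSpec:
    return ArchitectureSpec(n_individuals=2_000, n_snps=200, n_chrom=10)


@pytest.fixture(scope="session")
def small_world(small_arch):
    """A modest founder population with drawn effects and traits, reused by
    tests that only need a plausible random-mating world."""
    arch = draw_effects(small_arch, seed=11)
    pop = init_founders(arch, seed=12)
    traits = compute_traits(pop, arch)
    return arch, pop, traits
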