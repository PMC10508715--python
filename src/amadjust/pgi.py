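"""Polygenic-index (PGI) weights with controlled error and per-chromosome scores.

A PGI approximates a trait's additive genetic factor with a weighted sum of
allele counts.  Real weights are estimated with error; here the error level is
a single tunable fraction ``phi``: the weight for SNP j is

    w_j = phi * E_j + (1 - phi) * beta_j,      E_j ~ N(0, 1) iid,

so ``phi = 0`` reproduces the true effects and ``phi = 1`` is pure noise.
Error draws are independent across SNPs and between traits.

Scores are kept unstandardized: the adjustment factors downstream are ratios
of covariances, so any common scale cancels where it must.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PGIWeightSet",
    "ChromScoreMatrix",
    "noisy_weights",
    "chrom_scores",
    "attenuation_map",
    "phi_from_attenuation",
]


@dataclass
class PGIWeightSet:
    """Weights for one trait, with the error level and draws that built them."""

    weights: np.ndarray
    phi: float
    errors: np.ndarray | None = None
    beta: np.ndarray | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ChromScoreMatrix:
    """Per-individual, per-chromosome PGI values for one trait.

    ``scores[:, k]`` is the PGI restricted to SNPs on ``chroms[k]``; rows sum
    to the genome-wide score exactly.
    """

    scores: np.ndarray
    chroms: np.ndarray
    trait: str = ""

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_chrom(self) -> int:
        return self.scores.shape[1]

    @property
    def total(self) -> np.ndarray:
        """Genome-wide score (row sums across chromosomes)."""
        return self.scores.sum(axis=1)

    def chrom_column(self, chrom_labels: np.ndarray) -> np.ndarray:
        """Column position in ``scores`` for each entry of ``chrom_labels``."""
        pos = {int(c): i for i, c in enumerate(self.chroms)}
        try:
            return np.array([pos[int(c)] for c in chrom_labels])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unknown chromosome label {exc.args[0]}") from exc


def noisy_weights(beta: np.ndarray, phi: float, seed: int | None = None) -> PGIWeightSet:
    """Corrupt true effects into PGI weights: ``w = phi*E + (1-phi)*beta``."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    beta = np.asarray(beta, float)
    rng = np.random.default_rng(seed)
    errors = rng.standard_normal(len(beta))
    weights = phi * errors + (1.0 - phi) * beta
    return PGIWeightSet(weights=weights, phi=phi, errors=errors, beta=beta, seed=seed)


def chrom_scores(pop, wset, trait: str = "") -> ChromScoreMatrix:
    """Compute chromosome-specific scores ``sum_{j on k} w_j x_j``.

    ``wset`` may be a :class:`PGIWeightSet` or a plain weight vector; ``pop``
    is a :class:`~amadjust.sim.PopulationState`.
    """
    w = np.asarray(getattr(wset, "weights", wset), float)
    if len(w) != pop.n_snps:
        raise ValueError(
            f"weight vector length {len(w)} does not match SNP count {pop.n_snps}"
        )
    from .sim import _block_weight_matrix

    chroms = np.unique(pop.chrom_of_snp)
    x = pop.genotypes.astype(np.float64, copy=False)
    scores = x @ _block_weight_matrix(pop.chrom_of_snp, w)
    return ChromScoreMatrix(scores=scores, chroms=chroms, trait=trait)


def attenuation_map(phi: float) -> float:
    """Attenuation ``rho`` of a trait-on-PGI regression implied by error ``phi``.

    With the equal-variance error model above and a variance-standardized PGI,
    the regression coefficient of a trait on its PGI shrinks by

        rho(phi) = (1 - phi) / sqrt(phi**2 + (1 - phi)**2)

    relative to using the true additive genetic factor.  Monotone decreasing,
    with rho(0)=1 and rho(1)=0.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return (1.0 - phi) / np.sqrt(phi**2 + (1.0 - phi) ** 2)


def phi_from_attenuation(rho: float) -> float:
    """Inverse of :func:`attenuation_map` on [0, 1]."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if rho == 0.0:
        return 1.0
    t = np.sqrt(1.0 / rho**2 - 1.0)
    return float(t / (1.0 + t))
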