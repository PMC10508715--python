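"""Closed-form one-generation theory of assortative mating.

Mates are assumed to sort on latent traits S_m (females) and S_p (males)
whose projections onto the observed treatment (Z) and outcome (Y) traits have
coefficients theta_mZ, theta_mY, theta_pZ, theta_pY — the *sorting
parameters*.  After a single generation of sorting, the excess genetic
variance, the genetic correlation, the per-SNP GWAS bias and the expected MR
ratio have closed forms in three special scenarios:

* ``sort_Z``  — sorting only on the treatment (theta_mY = theta_pY = 0),
* ``sort_Y``  — sorting only on the outcome   (theta_mZ = theta_pZ = 0),
* ``cross``   — mothers sort on Z, fathers on Y (theta_mY = theta_pZ = 0).

All quantities are on the standardized scale (unit panmictic phenotypic
variance); they depend only on the sorting parameters, the panmictic
heritabilities h_Z^2, h_Y^2, and the panmictic genetic covariance rho_ZY and
correlation r_ZY — not on any other feature of the genetic architecture.
GWAS bias is linear in (beta_jZ, beta_jY).

The overall scale of the sorting parameters depends on how the latent-trait
matching is normalized, which is why simulation-versus-theory comparisons go
through a single *compound* parameter per scenario, calibrated from the
observed excess variance (:func:`calibrate_compound`) and then plugged into
the ``*_from_compound`` predictors: the unknown normalization cancels.

Two table cells in the source material are typographically corrupted and are
implemented with the symmetric theta-product restored (the only form
consistent with the neighboring cells and the theta = 0 limit); the MR-ratio
row, printed without thetas, is implemented with the theta-products restored
so that each cell is the ratio of the row's biased expected GWAS coefficients
for an exclusion-satisfying SNP — at theta-product 1 it reproduces the
printed forms exactly.  The cross-trait row's excess-variance and bias-Z
cells are implemented as printed (see docs/methods.md for the flagged
asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "TheoryPrediction",
    "SCENARIOS",
    "excess_variance",
    "rg_one_generation",
    "gwas_bias_one_generation",
    "mr_ratio_one_generation",
    "selection_bias_condition",
    "within_chrom_fraction",
    "calibrate_compound",
    "rg_from_compound",
    "gwas_bias_from_compound",
    "mr_ratio_from_compound",
    "predict",
]

SCENARIOS = ("sort_Z", "sort_Y", "cross")


@dataclass(frozen=True)
class TheoryParams:
    """Sorting parameters and panmictic moments on the standardized scale."""

    theta_mz: float = 0.0
    theta_my: float = 0.0
    theta_pz: float = 0.0
    theta_py: float = 0.0
    h2_z: float = 1.0
    h2_y: float = 1.0
    rho_zy: float = 0.0
    r_zy: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name, h2 in (("h2_z", self.h2_z), ("h2_y", self.h2_y)):
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {h2}")
        if abs(self.r_zy) > 1.0:
            raise ValueError("|r_zy| must be <= 1")
        bound = float(np.sqrt(self.h2_z * self.h2_y))
        if abs(self.rho_zy) > bound + 1e-9:
            raise ValueError(
                f"|rho_zy| = {abs(self.rho_zy)} exceeds sqrt(h2_z*h2_y) = {bound}"
            )


@dataclass
class TheoryPrediction:
    scenario: str
    excess_var_z: float
    excess_var_y: float
    rg_after: float
    mr_ratio: float


def _check_scenario(params: TheoryParams, scenario: str) -> None:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    zeroed = {
        "sort_Z": (("theta_my", params.theta_my), ("theta_py", params.theta_py)),
        "sort_Y": (("theta_mz", params.theta_mz), ("theta_pz", params.theta_pz)),
        "cross": (("theta_my", params.theta_my), ("theta_pz", params.theta_pz)),
    }[scenario]
    for name, val in zeroed:
        if val != 0.0:
            raise ValueError(f"scenario {scenario!r} requires {name} = 0, got {val}")


def excess_variance(params: TheoryParams, scenario: str) -> tuple[float, float]:
    """Excess genetic variance of (Z, Y) after one generation of sorting,
    relative to the panmictic variance, on the standardized scale."""
    _check_scenario(params, scenario)
    p = params
    if scenario == "sort_Z":
        q = p.theta_mz * p.theta_pz
        return 2 * q * p.h2_z**2, 2 * q * p.rho_zy**2
    if scenario == "sort_Y":
        q = p.theta_my * p.theta_py
        return 2 * q * p.rho_zy**2, 2 * q * p.h2_y**2
    # cross: both cells as printed in the source table (flagged: an
    # independent re-derivation puts h2_z in the Z cell; identical at h2=1)
    q = p.theta_mz * p.theta_py
    val = 2 * q * p.h2_y * p.rho_zy
    return val, val


def rg_one_generation(params: TheoryParams, scenario: str) -> float:
    """Genetic correlation after one generation of sorting.

    The single-trait cells are r * sqrt(1 + c) / sqrt(1 + c r^2) with
    c = 2 theta_m theta_p h^2 of the sorted trait: the covariance grows by the
    factor (1 + c) while the sorted trait's variance grows by the same factor
    and the other trait's by (1 + c r^2), and the correlation divides by the
    *root* of the variance product.  (The source table prints the cell without
    the radicals, but that is inconsistent with its own excess-variance cells
    and with the simulator; the same extraction strips radicals from the
    genetic-correlation definition itself.)  The cross-trait cell needs no
    radical at h^2 = 1 because both variances grow by the same factor.
    """
    _check_scenario(params, scenario)
    p = params
    r = p.r_zy
    if scenario == "sort_Z":
        c = 2 * p.theta_mz * p.theta_pz * p.h2_z
        return r * np.sqrt(1 + c) / np.sqrt(1 + c * r**2)
    if scenario == "sort_Y":
        c = 2 * p.theta_my * p.theta_py * p.h2_y
        return r * np.sqrt(1 + c) / np.sqrt(1 + c * r**2)
    # cross: r(1 + q(r + 1/r)) / (1 + 2qr) written without the 1/r singularity
    q = p.theta_mz * p.theta_py * np.sqrt(p.h2_z * p.h2_y)
    den = 1 + 2 * q * r
    if den == 0:
        raise ZeroDivisionError("degenerate cross-trait parameters (denominator 0)")
    return (r + q * (r**2 + 1)) / den


def gwas_bias_one_generation(
    params: TheoryParams,
    beta_jz: float | np.ndarray,
    beta_jy: float | np.ndarray,
    scenario: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected one-generation bias of the GWAS coefficients of SNP j on
    (Z, Y), as a linear function of the SNP's panmictic effects."""
    _check_scenario(params, scenario)
    p = params
    bz = np.asarray(beta_jz, float)
    by = np.asarray(beta_jy, float)
    if scenario == "sort_Z":
        q = p.theta_mz * p.theta_pz
        return 2 * bz * q * p.h2_z, 2 * bz * q * p.rho_zy
    if scenario == "sort_Y":
        q = p.theta_my * p.theta_py
        return 2 * by * q * p.rho_zy, 2 * by * q * p.h2_y
    # cross: both cells as printed (flagged duplication; see module docstring)
    q = p.theta_mz * p.theta_py
    val = bz * q * p.h2_y + by * q * p.rho_zy
    return val, val


def mr_ratio_one_generation(params: TheoryParams, scenario: str) -> float:
    """Expected infinite-sample MR ratio for an exclusion-satisfying SNP
    (beta_jY = gamma * beta_jZ) after one generation of sorting.

    Implemented as the ratio of the scenario's biased expected GWAS
    coefficients; with the theta-product equal to 1 this reproduces the
    printed closed forms (e.g. sort_Z: (gamma + 2 rho)/(1 + 2 h_Z^2)).
    """
    _check_scenario(params, scenario)
    p = params
    g = p.gamma
    if scenario == "sort_Z":
        q = p.theta_mz * p.theta_pz
        den = 1 + 2 * q * p.h2_z
        num = g + 2 * q * p.rho_zy
    elif scenario == "sort_Y":
        q = p.theta_my * p.theta_py
        den = 1 + 2 * q * g * p.rho_zy
        num = g * (1 + 2 * q * p.h2_y)
    else:
        q = p.theta_mz * p.theta_py
        den = 1 + q * (g * p.h2_z + p.rho_zy)
        num = g + q * (p.h2_y + g * p.rho_zy)
    if den == 0:
        raise ZeroDivisionError("MR-ratio denominator is zero for these parameters")
    return num / den


def selection_bias_condition(params: TheoryParams, tol: float = 1e-12) -> bool:
    """Whether SNP-selection bias is expected in an MR study.

    True iff (theta_mZ theta_pY + theta_pZ theta_mY) h_Z^2
             + 2 theta_mY theta_pY rho_ZY != 0 (within ``tol``): the treatment
    GWAS bias then depends on the SNP's outcome effect, so
    significance-selected instruments over-represent high-MR-ratio SNPs.
    """
    p = params
    val = (p.theta_mz * p.theta_py + p.theta_pz * p.theta_my) * p.h2_z
    val += 2 * p.theta_my * p.theta_py * p.rho_zy
    return abs(val) > tol


def within_chrom_fraction(snp_counts) -> float:
    """Expected share of SNP-pair (co)variance contributions that lie within
    chromosomes: sum_j M_j^2 / (sum_j M_j)^2 for per-chromosome counts M_j.

    Equals 1/C for C equal chromosomes; roughly 6% for the human common-SNP
    chromosome sizes.  Its complement is the share the cross-chromosome
    adjustment can see.
    """
    counts = np.asarray(snp_counts, float)
    if counts.size == 0:
        raise ValueError("snp_counts must be non-empty")
    if np.any(counts <= 0):
        raise ValueError("snp_counts must be positive")
    return float((counts**2).sum() / counts.sum() ** 2)


# ---------------------------------------------------------------------------
# Compound-parameter bridge between the simulator and the closed forms.
#
# The compound parameter is the theta-product combination that multiplies each
# row: c = 2 theta_mZ theta_pZ h_Z^2 (sort_Z), c = 2 theta_mY theta_pY h_Y^2
# (sort_Y), q = theta_mZ theta_pY h_Z h_Y (cross).  Calibrating it from the
# observed excess variance makes every other prediction parameter-free.
# ---------------------------------------------------------------------------


def calibrate_compound(excess_var: float, params: TheoryParams, scenario: str) -> float:
    """Compound sorting parameter implied by an observed excess variance.

    ``excess_var`` is the excess genetic variance (standardized scale) of the
    sorted trait after one generation: Z for ``sort_Z``, Y for ``sort_Y``,
    either trait for ``cross`` (whose printed cells are equal).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    p = params
    if scenario == "sort_Z":
        return excess_var / p.h2_z
    if scenario == "sort_Y":
        return excess_var / p.h2_y
    if p.rho_zy == 0:
        raise ValueError("cross-trait calibration requires a nonzero rho_zy")
    return excess_var * np.sqrt(p.h2_z) / (2 * np.sqrt(p.h2_y) * p.rho_zy)


def rg_from_compound(c: float, params: TheoryParams, scenario: str) -> float:
    """One-generation genetic correlation predicted from the compound."""
    r = params.r_zy
    if scenario in ("sort_Z", "sort_Y"):
        return r * np.sqrt(1 + c) / np.sqrt(1 + c * r**2)
    if scenario != "cross":
        raise ValueError(f"unknown scenario {scenario!r}")
    return (r + c * (r**2 + 1)) / (1 + 2 * c * r)


def gwas_bias_from_compound(
    c: float,
    params: TheoryParams,
    beta_jz: float | np.ndarray,
    beta_jy: float | np.ndarray,
    scenario: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP GWAS biases predicted from the compound parameter."""
    p = params
    bz = np.asarray(beta_jz, float)
    by = np.asarray(beta_jy, float)
    if scenario == "sort_Z":
        return c * bz, c * bz * p.rho_zy / p.h2_z
    if scenario == "sort_Y":
        return c * by * p.rho_zy / p.h2_y, c * by
    if scenario != "cross":
        raise ValueError(f"unknown scenario {scenario!r}")
    tt = c / np.sqrt(p.h2_z * p.h2_y)  # theta_mZ * theta_pY
    val = tt * (bz * p.h2_y + by * p.rho_zy)  # as printed: identical for Z and Y
    return val, val


def mr_ratio_from_compound(c: float, params: TheoryParams, scenario: str) -> float:
    """Expected MR ratio for a valid SNP predicted from the compound."""
    p = params
    g = p.gamma
    if scenario == "sort_Z":
        return (g + c * p.rho_zy / p.h2_z) / (1 + c)
    if scenario == "sort_Y":
        return g * (1 + c) / (1 + c * g * p.rho_zy / p.h2_y)
    if scenario != "cross":
        raise ValueError(f"unknown scenario {scenario!r}")
    tt = c / np.sqrt(p.h2_z * p.h2_y)
    return (g + tt * (p.h2_y + g * p.rho_zy)) / (1 + tt * (g * p.h2_z + p.rho_zy))


def predict(params: TheoryParams, scenario: str) -> TheoryPrediction:
    """All scalar one-generation predictions for one scenario."""
    dvz, dvy = excess_variance(params, scenario)
    return TheoryPrediction(
        scenario=scenario,
        excess_var_z=float(dvz),
        excess_var_y=float(dvy),
        rg_after=float(rg_one_generation(params, scenario)),
        mr_ratio=float(mr_ratio_one_generation(params, scenario)),
    )
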