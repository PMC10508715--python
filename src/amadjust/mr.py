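"""Mendelian-randomization estimators and instrument selection.

MR infers the causal effect of a treatment trait on an outcome from SNP
summary statistics.  The per-SNP "MR ratio" is beta_Y,j / beta_Z,j; the
estimators here combine ratios by the median, a rectangular-kernel mode, or
the Egger regression of outcome betas on treatment betas with an intercept.

Under assortative mating no SNP satisfies the exclusion restriction exactly,
and significance-based instrument selection preferentially admits SNPs whose
treatment association was inflated through their outcome effect (SNP-selection
bias); the estimators are provided both for unadjusted scans and for scans
adjusted with the per-SNP cross-chromosome factors (adjusted MR uses the
median only, which is most robust to the unstable ratios the adjustment can
produce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MREstimate",
    "bonferroni_cutoff",
    "select_instruments",
    "mr_ratios",
    "mr_median",
    "mr_egger",
    "mr_mode",
    "adjusted_mr",
]


@dataclass
class MREstimate:
    method: str
    estimate: float
    intercept: float | None = None
    n_instruments: int = 0
    instruments: list = field(default_factory=list)
    selection_rule: str = ""
    adjusted: bool = False
    n_dropped: int = 0


def bonferroni_cutoff(n_snps: int, alpha: float = 0.05) -> float:
    """Family-wise p-value threshold alpha / n_snps (0.05/2000 = 2.5e-5)."""
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    return alpha / n_snps


def select_instruments(
    gwas_z: pd.DataFrame, rule: str = "p_threshold", cutoff: float | None = None
) -> list:
    """SNPs passing an instrument-strength rule on the treatment scan.

    ``rule="p_threshold"`` keeps SNPs with P < cutoff (default: the Bonferroni
    threshold 0.05 / number of SNPs); ``rule="f_threshold"`` keeps SNPs with
    F > cutoff (default 10, the weak-instrument convention).  Rows flagged
    invalid (e.g. monomorphic SNPs) are never selected.  An empty selection is
    an error naming the rule and cutoff.
    """
    valid = gwas_z["VALID"].to_numpy(bool) if "VALID" in gwas_z else np.ones(len(gwas_z), bool)
    if rule == "p_threshold":
        if cutoff is None:
            cutoff = bonferroni_cutoff(len(gwas_z))
        keep = valid & (gwas_z["P"].to_numpy(float) < cutoff)
    elif rule == "f_threshold":
        if cutoff is None:
            cutoff = 10.0
        keep = valid & (gwas_z["F"].to_numpy(float) > cutoff)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    ids = list(gwas_z.loc[keep, "SNP"])
    if not ids:
        raise ValueError(f"no instruments pass rule={rule!r} at cutoff={cutoff}")
    return ids


def _aligned_betas(
    gwas_y: pd.DataFrame, gwas_z: pd.DataFrame, instruments: list, column: str = "BETA"
) -> tuple[np.ndarray, np.ndarray, list]:
    by = gwas_y.set_index("SNP")[column]
    bz = gwas_z.set_index("SNP")[column]
    missing = [s for s in instruments if s not in by.index or s not in bz.index]
    if missing:
        raise KeyError(f"instruments absent from a GWAS table: {missing[:5]}")
    return by.loc[instruments].to_numpy(float), bz.loc[instruments].to_numpy(float), list(instruments)


def mr_ratios(
    gwas_y: pd.DataFrame, gwas_z: pd.DataFrame, instruments: list, column: str = "BETA"
) -> tuple[np.ndarray, list, int]:
    """Per-instrument MR ratios beta_Y / beta_Z.

    Instruments with a zero (or non-finite) treatment beta are dropped and
    counted; returns (ratios, kept instrument ids, number dropped).
    """
    by, bz, ids = _aligned_betas(gwas_y, gwas_z, instruments, column)
    ok = np.isfinite(by) & np.isfinite(bz) & (bz != 0)
    n_dropped = int((~ok).sum())
    ratios = by[ok] / bz[ok]
    kept = [s for s, k in zip(ids, ok) if k]
    return ratios, kept, n_dropped


def mr_median(ratios: np.ndarray) -> MREstimate:
    """Sample median of the MR ratios (midpoint convention for even counts)."""
    ratios = np.asarray(ratios, float)
    if ratios.size == 0:
        raise ValueError("mr_median requires at least one ratio")
    return MREstimate(method="median", estimate=float(np.median(ratios)), n_instruments=len(ratios))


def mr_egger(gwas_y: pd.DataFrame, gwas_z: pd.DataFrame, instruments: list) -> MREstimate:
    """Egger regression: outcome betas on treatment betas with an intercept.

    Each instrument is first oriented so its treatment beta is non-negative
    (flipping both betas), making the estimate invariant to allele coding.
    Requires at least 3 instruments.
    """
    by, bz, ids = _aligned_betas(gwas_y, gwas_z, instruments)
    if len(ids) < 3:
        raise ValueError(f"mr_egger requires >= 3 instruments, got {len(ids)}")
    flip = np.sign(bz)
    flip[flip == 0] = 1.0
    bz_o = bz * flip
    by_o = by * flip
    fit = sm.OLS(by_o, sm.add_constant(bz_o)).fit()
    return MREstimate(
        method="egger",
        estimate=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n_instruments=len(ids),
        instruments=ids,
    )


def mr_mode(ratios: np.ndarray, bandwidth: float = 0.1) -> MREstimate:
    """Mode of the MR-ratio distribution under a rectangular kernel.

    The density is evaluated on a grid from min(ratios)-bandwidth to
    max(ratios)+bandwidth at step bandwidth/10, counting ratios within the
    kernel half-width (= bandwidth) of each grid point; ties take the midpoint
    of the argmax set.
    """
    ratios = np.asarray(ratios, float)
    if ratios.size == 0:
        raise ValueError("mr_mode requires at least one ratio")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo = ratios.min() - bandwidth
    hi = ratios.max() + bandwidth
    step = bandwidth / 10.0
    grid = np.arange(lo, hi + step / 2.0, step)
    counts = (np.abs(ratios[None, :] - grid[:, None]) <= bandwidth).sum(axis=1)
    top = np.flatnonzero(counts == counts.max())
    estimate = float((grid[top[0]] + grid[top[-1]]) / 2.0)
    return MREstimate(method="mode", estimate=estimate, n_instruments=len(ratios))


def adjusted_mr(
    adjusted_gwas_y: pd.DataFrame, adjusted_gwas_z: pd.DataFrame, instruments: list
) -> MREstimate:
    """MR-Median on AM-adjusted GWAS coefficients.

    Uses the BETA_ADJ columns produced by :func:`amadjust.adjust.adjust_gwas`.
    Instruments whose *treatment*-side adjustment factor was flagged
    (near-zero expected denominator) are excluded before taking ratios: an
    instrument's relevance lives on the treatment side, so an ill-conditioned
    K there poisons the ratio's denominator.  The outcome-side factor is
    applied as-is — for a valid instrument with no outcome effect it is
    intrinsically a ratio of small values, and the median is the defense
    against the resulting instability (which is why only the median is
    offered on adjusted scans).
    """
    for name, tab in (("outcome", adjusted_gwas_y), ("treatment", adjusted_gwas_z)):
        if "BETA_ADJ" not in tab:
            raise ValueError(f"adjusted {name} table lacks BETA_ADJ; run adjust_gwas first")
    vz = adjusted_gwas_z.set_index("SNP")["VALID"]
    usable = [s for s in instruments if bool(vz.get(s, False))]
    n_flagged = len(instruments) - len(usable)
    if not usable:
        raise ValueError("every instrument was flagged by the adjustment")
    ratios, kept, n_zero = mr_ratios(adjusted_gwas_y, adjusted_gwas_z, usable, column="BETA_ADJ")
    est = mr_median(ratios)
    return MREstimate(
        method="median",
        estimate=est.estimate,
        n_instruments=len(kept),
        instruments=kept,
        adjusted=True,
        n_dropped=n_flagged + n_zero,
    )
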