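"""Per-SNP association scans and PGI regressions.

``run_gwas`` regresses a quantitative trait on each SNP separately (with an
intercept) by ordinary least squares, the summary-statistic input consumed by
the adjustment and Mendelian-randomization modules.  The scan is computed in
closed form across all SNPs at once; two-sided p-values come from the t
reference distribution with n-2 degrees of freedom.

Monomorphic SNPs are not dropped: their rows carry undefined statistics and
``VALID=False`` so downstream selection can skip them explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["run_gwas", "pgi_regression", "default_snp_ids"]

GWAS_COLUMNS = ["SNP", "CHR", "BETA", "SE", "T", "F", "P", "N", "FREQ", "VALID"]


def default_snp_ids(m: int) -> list[str]:
    """Opaque SNP identifiers used when the caller supplies none."""
    width = len(str(m))
    return [f"snp{j + 1:0{width}d}" for j in range(m)]


def run_gwas(trait: np.ndarray, pop, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """OLS scan of ``trait`` on every SNP of ``pop`` separately.

    Returns a table with columns SNP, CHR, BETA, SE, T, F, P, N, FREQ, VALID,
    one row per SNP in genotype order.  F equals T**2 (single regressor).
    """
    y = np.asarray(trait, float)
    n = pop.n_individuals
    if len(y) != n:
        raise ValueError(f"trait length {len(y)} does not match {n} individuals")
    x = pop.genotypes

    # centered-y algebra avoids materializing a centered genotype matrix
    # (sum x*(y-ybar) equals the fully centered cross product), and the
    # genotype moments are exact integer counts of dosages 1 and 2
    yc = y - y.mean()
    n1 = (x == 1).sum(axis=0)
    n2 = (x == 2).sum(axis=0)
    xm = (n1 + 2.0 * n2) / n
    sxx = (n1 + 4.0 * n2) - n * xm**2
    sxy = yc @ x.astype(np.float64, copy=False)
    syy = float(yc @ yc)

    valid = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(valid, sxy / sxx, np.nan)
        sse = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = sse / (n - 2)
        se = np.sqrt(np.where(valid, sigma2 / sxx, np.nan))
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    if snp_ids is None:
        snp_ids = default_snp_ids(pop.n_snps)
    return pd.DataFrame(
        {
            "SNP": snp_ids,
            "CHR": np.asarray(pop.chrom_of_snp, int),
            "BETA": beta,
            "SE": se,
            "T": t,
            "F": t**2,
            "P": p,
            "N": n,
            "FREQ": xm / 2.0,
            "VALID": valid,
        }
    )


def pgi_regression(trait: np.ndarray, score: np.ndarray) -> tuple[float, float]:
    """OLS slope (with intercept) of ``trait`` on a polygenic score.

    Returns ``(slope, se)``.  The slope equals Cov(trait, score)/Var(score);
    under assortative mating its numerator carries the same AM-induced
    cross-chromosome LD terms as the genetic covariance.
    """
    trait = np.asarray(trait, float)
    score = np.asarray(score, float)
    if len(trait) != len(score):
        raise ValueError("trait and score must have equal length")
    if score.std() == 0:
        raise ValueError("score is constant; slope undefined")
    res = stats.linregress(score, trait)
    return float(res.slope), float(res.stderr)
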