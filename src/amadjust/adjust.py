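"""Cross-chromosome adjustment of genetic (co)variance, correlation and GWAS.

Because chromosomes segregate independently, covariance between polygenic
scores built from *different* chromosomes can only come from assortative
mating (or other sources of cross-locus dependence such as stratification),
never from linkage.  The estimators here exploit that:

* ``K_hat_{Z,Y}`` — the fraction of the covariance between two traits' scores
  that lies within chromosomes:

      K_hat = sum_k Cov(g_kZ, g_kY) /
              [ sum_k Cov(g_kZ, g_kY) + sum_{k != l} Cov(g_kZ, g_lY) ]

  where g_k* are chromosome-specific PGIs.  The denominator equals the
  covariance of the genome-wide scores by bilinearity.
* ``A_hat = K_hat_ZY / sqrt(K_hat_ZZ * K_hat_YY)`` — the fraction of the
  genetic correlation due to within-chromosome LD.  Multiplying a genetic
  correlation estimate by A_hat adjusts it toward its random-mating value;
  1 - A_hat estimates the fraction driven by AM.
* ``K_hat_j`` — the per-SNP analogue (own-chromosome covariance of the SNP
  with the trait PGI over the total), used to adjust GWAS coefficients as
  ``beta_adj = beta * K_hat_j``.

None of the ratios is clipped to [0, 1]: raw values are reported so the
bootstrap sampling distributions stay honest.  Uncertainty comes from a
percentile bootstrap over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .pgi import ChromScoreMatrix

__all__ = [
    "AdjustmentEstimate",
    "BootstrapResult",
    "chrom_cross_cov",
    "k_hat_pair",
    "a_hat",
    "adjust_rg",
    "k_hat_snps",
    "adjust_gwas",
    "bootstrap",
    "estimate_adjustment",
]


def _score_array(scores) -> np.ndarray:
    return scores.scores if isinstance(scores, ChromScoreMatrix) else np.asarray(scores, float)


def chrom_cross_cov(scores_z, scores_y) -> np.ndarray:
    """C x C matrix of sample covariances Cov(g_kZ, g_lY), ddof=1."""
    a = _score_array(scores_z)
    b = _score_array(scores_y)
    if a.shape != b.shape:
        raise ValueError("score matrices must share shape (individuals x chromosomes)")
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return ac.T @ bc / (n - 1)


def k_hat_pair(scores_z, scores_y) -> float:
    """Within-chromosome fraction of the covariance between two score sets.

    The numerator sums the diagonal (own-chromosome) covariances; the
    denominator adds every ordered cross-chromosome pair, and equals the
    covariance of the genome-wide scores to floating-point accuracy.
    """
    cov = chrom_cross_cov(scores_z, scores_y)
    if cov.shape[0] < 2:
        raise ValueError("at least two chromosomes are required")
    num = float(np.trace(cov))
    den = float(cov.sum())
    if den == 0.0:
        raise ZeroDivisionError("total score covariance is zero; K undefined")
    return num / den


def a_hat(k_zy: float, k_zz: float, k_yy: float) -> float:
    """Adjustment factor for the genetic correlation."""
    prod = k_zz * k_yy
    if prod <= 0:
        raise ValueError(f"K_ZZ*K_YY must be positive, got {prod}")
    return k_zy / float(np.sqrt(prod))


def adjust_rg(rg_est: float, a: float) -> tuple[float, float]:
    """Return (adjusted genetic correlation, fraction due to AM).

    The adjusted value ``rg_est * a`` estimates what the genetic correlation
    would be in a randomly mating population; ``1 - a`` is the estimated
    fraction of the observed correlation driven by AM.
    """
    return rg_est * a, 1.0 - a


def k_hat_snps(
    pop,
    scores: ChromScoreMatrix,
    weights: np.ndarray,
    min_denom_se: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP adjustment factors K_hat_j and a validity mask.

    K_hat_j = Cov(x_j, own-chromosome PGI) / sum_k Cov(x_j, chromosome-k PGI).

    The denominator is a ratio of small covariances whose sampling SE,
    sqrt(Var(x_j) Var(g_hat) / n), is often comparable to its random-mating
    expectation ``w_j Var(x_j)``; ratios with such denominators are
    ill-conditioned (their relative bias is of order (SE/denominator)^2).  A
    SNP is therefore flagged invalid unless its *expected* denominator clears
    ``min_denom_se`` sampling SEs — a screen on the weight, deliberately
    independent of the realized noise so that flagging does not itself distort
    the retained ratios — or when the SNP is monomorphic.  Flagged SNPs keep
    their raw ratio but must be excluded downstream.
    """
    x = pop.genotypes.astype(np.float64, copy=False)
    s = scores.scores
    n, m = x.shape
    w = np.asarray(getattr(weights, "weights", weights), float)
    if len(w) != m:
        raise ValueError("weight vector length does not match the SNP count")
    # centering the scores alone suffices: sum x*(s-sbar) = sum (x-xbar)(s-sbar)
    sc = s - s.mean(axis=0)
    covs = x.T @ sc / (n - 1)  # M x C
    den = covs.sum(axis=1)
    own_col = scores.chrom_column(pop.chrom_of_snp)
    num = covs[np.arange(m), own_col]

    xm = x.mean(axis=0)
    var_x = (np.einsum("ij,ij->j", x, x) - n * xm**2) / (n - 1)
    total = scores.total
    var_total = float(total.var(ddof=1))
    se_den = np.sqrt(var_x * var_total / n)
    valid = (var_x > 0) & (np.abs(w) * var_x > min_denom_se * se_den)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = num / den
    return k, valid


def adjust_gwas(
    gwas: pd.DataFrame,
    pop,
    scores: ChromScoreMatrix,
    weights: np.ndarray,
    min_denom_se: float = 5.0,
) -> pd.DataFrame:
    """Attach per-SNP adjustment factors and adjusted coefficients to a scan.

    Adds columns K (the factor), BETA_ADJ = BETA * K, and ANDs the VALID flag
    with the denominator flag from :func:`k_hat_snps`.  Rows follow the
    genotype order of ``pop``, which must match the scan's row order.
    """
    if len(gwas) != pop.n_snps:
        raise ValueError("GWAS table and population disagree on SNP count")
    k, valid = k_hat_snps(pop, scores, weights, min_denom_se=min_denom_se)
    out = gwas.copy()
    out["K"] = k
    out["BETA_ADJ"] = out["BETA"] * k
    out["VALID"] = out["VALID"].to_numpy(bool) & valid
    return out


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary: SE and (2.5th, 97.5th) percentile CI."""

    replicates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_failed: int = 0


def bootstrap(
    statistic: Callable[[np.ndarray], float | np.ndarray],
    n: int,
    n_boot: int = 100,
    seed: int | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap over individuals.

    ``statistic`` receives an index array of length ``n`` (a resample of
    individuals with replacement, at full sample size) and returns a scalar or
    vector; any statistic recomputation — including rebuilding PGI scores —
    happens inside the callable.  Replicates where the statistic raises are
    recorded as missing and counted in ``n_failed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps.append(np.atleast_1d(np.asarray(statistic(idx), float)))
        except Exception:
            n_failed += 1
    if not reps:
        raise RuntimeError("statistic failed on every bootstrap resample")
    r = np.vstack(reps)
    se = r.std(axis=0, ddof=1)
    ci_low, ci_high = np.percentile(r, [2.5, 97.5], axis=0)
    return BootstrapResult(replicates=r, se=se, ci_low=ci_low, ci_high=ci_high, n_failed=n_failed)


_STAT_NAMES = ("k_zy", "k_zz", "k_yy", "a_zy", "fraction_due_to_am", "adjusted_rg")


@dataclass
class AdjustmentEstimate:
    """Point estimates and bootstrap uncertainty for the AM adjustment.

    Percentile CIs are recorded as computed; they are not forced to bracket
    the point estimate.
    """

    k_zy: float
    k_zz: float
    k_yy: float
    a_zy: float
    fraction_due_to_am: float
    adjusted_rg: float | None = None
    rg_input: float | None = None
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    n_failed: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "k_zy": self.k_zy,
            "k_zz": self.k_zz,
            "k_yy": self.k_yy,
            "a_zy": self.a_zy,
            "fraction_due_to_am": self.fraction_due_to_am,
            "adjusted_rg": self.adjusted_rg,
            "rg_input": self.rg_input,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        return out


def _adjustment_vector(sz: np.ndarray, sy: np.ndarray, rg_est: float | None) -> np.ndarray:
    kzy = k_hat_pair(sz, sy)
    kzz = k_hat_pair(sz, sz)
    kyy = k_hat_pair(sy, sy)
    a = a_hat(kzy, kzz, kyy)
    vals = [kzy, kzz, kyy, a, 1.0 - a]
    vals.append(rg_est * a if rg_est is not None else np.nan)
    return np.array(vals)


def estimate_adjustment(
    scores_z: ChromScoreMatrix,
    scores_y: ChromScoreMatrix,
    rg_est: float | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> AdjustmentEstimate:
    """Full adjustment pipeline on a pair of chromosome-score matrices.

    With ``n_boot > 0``, individuals are resampled with replacement ``n_boot``
    times (default protocol: 100 replicates, percentile 95% CI) and every
    quantity — the K factors, A, the AM fraction and the adjusted genetic
    correlation — is re-estimated per replicate.
    """
    sz = _score_array(scores_z)
    sy = _score_array(scores_y)
    point = _adjustment_vector(sz, sy, rg_est)
    est = AdjustmentEstimate(
        k_zy=float(point[0]),
        k_zz=float(point[1]),
        k_yy=float(point[2]),
        a_zy=float(point[3]),
        fraction_due_to_am=float(point[4]),
        adjusted_rg=None if rg_est is None else float(point[5]),
        rg_input=rg_est,
        seed=seed,
    )
    if n_boot:
        res = bootstrap(
            lambda idx: _adjustment_vector(sz[idx], sy[idx], rg_est),
            n=sz.shape[0],
            n_boot=n_boot,
            seed=seed,
        )
        names = _STAT_NAMES if rg_est is not None else _STAT_NAMES[:-1]
        est.se = {name: float(res.se[i]) for i, name in enumerate(names)}
        est.ci = {
            name: (float(res.ci_low[i]), float(res.ci_high[i])) for i, name in enumerate(names)
        }
        est.n_boot = n_boot
        est.n_failed = res.n_failed
    return est
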