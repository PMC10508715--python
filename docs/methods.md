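# Methods

## The problem

Assortative mating (AM) — any process that makes mates' traits or genotypes
correlated, whether direct sorting, geography or stratification — builds
correlations between genotypes at *unlinked* loci (gametic-phase
disequilibrium) that compound over generations.  Genetic variances, genetic
correlations, PGI regression coefficients, GWAS associations and Mendelian
randomization (MR) ratios all absorb these cross-locus covariance terms, so
their values in a sorting population differ from what they would be under
random mating.  Correcting them from theory requires knowing the historical
sorting process; this package instead *measures* the AM-induced component
directly, using the fact that chromosomes segregate independently: any
covariance between polygenic indexes built from different chromosomes can
only come from AM-type processes, never from linkage.

## Estimators

Let ĝ_kZ be the PGI for trait Z restricted to chromosome k (an unstandardized
weighted allele-count sum).  The within-chromosome fraction of the covariance
between two traits' genetic factors is estimated by

    K̂_ZY = Σ_k Cov(ĝ_kZ, ĝ_kY) / [ Σ_k Cov(ĝ_kZ, ĝ_kY) + Σ_{k≠ℓ} Cov(ĝ_kZ, ĝ_ℓY) ],

whose denominator equals Cov(ĝ_Z, ĝ_Y) of the genome-wide scores by
bilinearity (an identity asserted in tests to floating-point accuracy).
Single-trait versions K̂_ZZ, K̂_YY use the same formula with both arguments
equal; the cross-chromosome sum runs over ordered pairs as the formula's
index set states, which double-counts the symmetric single-trait terms
consistently in numerator-free fashion (the denominator identity still
holds).  The genetic-correlation adjustment factor is

    Â = K̂_ZY / sqrt(K̂_ZZ · K̂_YY).

Multiplying a genetic-correlation estimate by Â adjusts it toward its
random-mating value; 1 − Â estimates the fraction of the correlation driven
by AM.  Under random mating all cross-chromosome terms have expectation zero
and Â = 1.  Ratios are reported unclipped so bootstrap distributions are
honest.  Note the two quantities exposed: `adjusted_rg = rg × Â` and
`fraction_due_to_am = 1 − Â`.

The per-SNP analogue for GWAS coefficients is

    K̂_j = Cov(x_j, ĝ on SNP j's own chromosome) / Σ_k Cov(x_j, ĝ_k),

with the adjusted coefficient β̂_adj = β̂ · K̂_j.  Although K̂_j is often
*labelled* the fraction due to cross-chromosome LD, the formula (own-
chromosome numerator) is the within-chromosome fraction; we implement the
formula as printed and treat the label as shorthand.

### Conditioning screen for K̂_j

K̂_j is a ratio of small covariances.  Its denominator has random-mating
expectation w_j·Var(x_j) and sampling SE ≈ sqrt(Var(x_j)·Var(ĝ)/n); whenever
these are comparable the ratio is ill-conditioned, with relative bias of
order (SE/denominator)².  A SNP is therefore flagged unless its *expected*
denominator clears `min_denom_se` (default 5) sampling SEs, bounding the
conditioning bias at roughly (1/5)² ≈ 4%.  Two design points matter:

* the screen uses the expected denominator (a function of the weight, which
  is data), not the realized one — screening on the realized denominator
  selects denominators co-inflated with their own noise and systematically
  attenuates the retained ratios (we measured ≈ 0.84 instead of ≈ 1 under
  random mating for realized-denominator screens at any multiplier);
* in adjusted MR the screen is applied to the treatment scan only.  An
  instrument's relevance is a treatment-side property; the outcome-side
  factor of a *valid* instrument (no outcome effect) is intrinsically a ratio
  of small values, and the median — the only estimator offered on adjusted
  scans — is the defense against the resulting instability.

### Why the adjustment is approximate

The proxy sees only cross-chromosome LD.  With C chromosomes of equal SNP
content, the within-chromosome share of SNP-pair contributions is
Σ M_k²/(Σ M_k)² = 1/C (5% at C = 20; about 6% for human common-SNP counts),
so roughly 1/C of every AM-induced inflation component survives the
adjustment.  Recovery tests therefore allow a mean residual up to about
2×(observed inflation)/C plus Monte-Carlo error instead of exactly zero (the
factor 2 accounts for the covariance inflation entering the correlation ratio
ahead of the half-compensating variance inflations).  With noisy weights the
adjustment stays mean-zero under random mating but *overcorrects* under
sorting, so 1 − Â is an upper bound on the AM contribution.

## PGI error model

Weights are corrupted as w_j = φ·E_j + (1−φ)·β_j with E_j ~ N(0,1) iid
(independent across SNPs and, by choice, between traits — the protocol is
silent on cross-trait error correlation).  For a variance-standardized PGI
the implied attenuation of a trait-on-PGI regression coefficient is

    ρ(φ) = (1−φ) / sqrt(φ² + (1−φ)²),

derived from the weight-error model and verified against a simulation oracle
(the printed φ↔ρ relation in the source material is typographically
corrupted; we ship the derived closed form with its inverse).  φ = 0.4 is the
benchmark error level of a current educational-attainment PGI.  Scores are
never standardized internally: every downstream quantity is a covariance
ratio in which common scale cancels.

## Simulator

The forward-time simulator is the package's test-data source and emulates the
validation conditions: 10,000 individuals, 2,000 SNPs on 20 equal
chromosomes, founder genotypes Binomial(2, 0.5), perfectly heritable traits
(h² < 1 is supported as an extension: Gaussian noise scaled once, in the
founder generation, to hit the target heritability and held fixed
thereafter), two offspring per pair, random half-split sexes, and free
recombination — every locus independent, so *all* emergent LD is AM-induced.
Mating mechanisms: `random`, `treatment` (both sexes ranked on Z and matched
rank-to-rank), `outcome` (ranked on Y), `cross_trait` (females on Z, males on
Y), `multi_trait` (each sex on a weighted sum of standardized traits,
default weights (1,1) — the source defers the exact definition, so this is
an implementation choice).  Rank ties are broken by a pre-drawn random
permutation; `match_noise` (default 0 = exact matching) perturbs sorting
scores to sweep AM strength.  Architectures: `full` pleiotropy (every SNP
bivariate-normal effects with target correlation), `none` (disjoint halves),
`partial` (default: 50% pleiotropic, 25% per trait-specific — also an
implementation choice where the source defers).  A causal effect γ of Z on Y
is supported (`causal_effect`), making the treatment-only SNPs valid MR
instruments with total outcome effects γβ_Z.

What the generator does *not* emulate: realistic allele-frequency spectra,
within-chromosome linkage, mutation/selection, incomplete heritability of
real traits, non-Gaussian effect sizes, or weight error that is correlated
with effects (LD-based estimation error).  Passing tests therefore show the
estimators behave as designed under the stated model, not that real-data
adjustments are unbiased — on real data 1 − Â remains an upper bound.

## One-generation closed forms

For mates sorting on latent traits S_m = θ_mZ Z + θ_mY Y + U_m (mothers) and
S_p likewise (fathers), with traits standardized to unit panmictic
phenotypic variance, three scenarios admit closed forms after one
generation: sorting on Z only, on Y only, and cross-trait (mothers on Z,
fathers on Y).  Writing c for the scenario's compound parameter
(2θ_mZθ_pZ h_Z², 2θ_mYθ_pY h_Y², or θ_mZθ_pY h_Z h_Y):

* excess genetic variance of the sorted trait: c·h² (and c·ρ²/h² for the
  other trait; the cross-trait cells are 2θ_mZθ_pY h_Y² ρ for both traits as
  printed — a re-derivation suggests h_Z² belongs in the Z cell, but the two
  coincide at h² = 1, the validation condition);
* genetic correlation: r·sqrt(1+c)/sqrt(1+c·r²) for single-trait sorting —
  the covariance grows by (1+c), the variances by (1+c) and (1+c·r²), and
  the correlation divides by the *root* of the variance product.  The source
  table prints this cell without the radicals, which is inconsistent with
  its own excess-variance cells and with the simulator (its extraction
  demonstrably strips radicals elsewhere, including from the definition of
  the genetic correlation itself); the radical-restored form matches the
  simulator to Monte-Carlo precision.  The cross-trait cell needs no radical
  at h² = 1 because both variances grow by the same factor, and is
  implemented as printed;
* GWAS bias, linear in (β_jZ, β_jY): e.g. sorting on Z gives
  (2β_jZθ_mZθ_pZ h_Z², 2β_jZθ_mZθ_pZ ρ); sorting on Y gives the mirror — its
  bias on the *treatment* scan, 2β_jYθ_mYθ_pY ρ, is the engine of
  SNP-selection bias.  The cross-trait bias cells are implemented as printed
  (identical for both traits), flagged as a suspected extraction duplicate;
* MR ratio of an exclusion-satisfying SNP (β_jY = γβ_jZ): the ratio of the
  row's biased expected coefficients, e.g. (γ + 2θ_mZθ_pZ ρ)/(1 + 2θ_mZθ_pZ
  h_Z²) for sorting on Z.  The printed cells carry no θs; restoring the
  θ-products makes each cell consistent with its row's bias cells and
  reproduces the printed forms at θ-product 1, while giving the correct
  panmictic limit (→ γ) at θ = 0.

Because the θ normalization of the latent-trait matching is not pinned down,
simulation-versus-theory comparisons calibrate the compound c from the
observed excess variance alone (`calibrate_compound`) — under exact rank
matching on a perfectly heritable trait c ≈ 0.5 — and then predict the
genetic correlation, the per-SNP biases and the MR ratio parameter-free.
This cross-validation is run for all three scenarios and across pleiotropy
modes (the predictions use only h², ρ, r: architecture independence).

SNP-selection bias is expected exactly when
(θ_mZθ_pY + θ_pZθ_mY)h_Z² + 2θ_mYθ_pY ρ ≠ 0 (tolerance 1e-12): cross-trait
sorting with a heritable treatment, or outcome sorting with genetically
correlated traits.

## Uncertainty

Standard errors and 95% CIs come from a percentile bootstrap: individuals
are resampled with replacement at full sample size, all scores and ratios
are recomputed per replicate (100 by default), and the 2.5th/97.5th
percentiles are reported.  CIs are recorded as computed and are not forced
to bracket the point estimate.  Replicates where a statistic fails are
recorded as missing and counted.

## Numerical and design choices

* Sample covariances use the n−1 denominator throughout.
* GWAS: closed-form vectorized per-SNP OLS with intercept; two-sided
  p-values from the t distribution with n−2 df; monomorphic SNPs are flagged
  rows (never silently dropped).
* Egger orientation: every instrument is recoded so its treatment beta is
  non-negative before the intercept regression, making the estimate
  invariant to allele coding; median and Egger are unweighted, as in the
  protocol.
* MR-Mode: rectangular kernel, half-width = bandwidth (default 0.1), grid
  step bandwidth/10 from min−bandwidth to max+bandwidth, ties resolved to
  the midpoint of the argmax plateau; the density is fit to unweighted
  ratios.
* Instrument rules: p < 0.05/M (Bonferroni, 2.5e-5 at M = 2,000) or F > 10;
  an empty selection is an explicit error naming the rule and cutoff.
* Traits are never re-standardized across generations; analysis code
  standardizes by founder-generation SDs where the standardized-scale theory
  is compared against simulation.
* Seeds: every stochastic step takes an explicit seed; multi-step pipelines
  derive 31-bit child seeds from one master generator, so identical configs
  are bit-identical.

## Problem sizes used in validation

The validation suite runs the estimators at the study conditions (10,000
individuals, 2,000 SNPs, 20 chromosomes): 20 replicate founder worlds for
the random-mating identities, 20 four-generation outcome-sorting worlds for
panmictic recovery (10 of them carrying the φ ∈ {0, 0.2, 0.4, 0.6, 0.8}
error sweep), one-generation theory checks with 2 worlds × 4 offspring
replicates per scenario-architecture cell — two worlds because the founder
baseline variance enters the compound calibration as a per-world offset that
replicate-averaging cannot remove, and the cross-trait calibration averages
both traits' (equal) excess-variance cells to halve that noise — (12
replicates at 40,000 individuals for the per-SNP bias regressions, where the
per-SNP signal must be resolved; their bias reference is
β_true + (β̂_founder − β_true)/2, because pre-existing LD between unlinked
loci halves each generation, so half of the founder scan's realized LD
deviation persists in the offspring scan — a transmission factor we measured
at 0.50 in random-mating rebreedings — and the per-SNP effects entering the
linear-bias design are the realized founder projections, since the model
defines effects as projections of the trait onto the genotypes of the
population at hand), 20
sorting plus 12 random-mating worlds for SNP-selection bias, and 40 founder
worlds of 100-replicate bootstraps for coverage.  These sizes were chosen to
keep Monte-Carlo error comfortably below each assertion's tolerance.

## Known limitations

* The adjustment leaves the within-chromosome (~1/C) share of AM-induced LD
  in place by construction, and with noisy weights is a deliberate
  overcorrection bound rather than an unbiased estimate.
* Adjusted MR remains exposed to SNP-selection bias (selection happens
  before adjustment) and is sensitive to PGI error; only the median variant
  is offered on adjusted scans.
* The one-generation closed forms cover the three special sorting scenarios
  with the latent-trait residual effects set to zero; general multi-
  generation recursions are out of scope.
* The dosage-TSV/weight-TSV dialect is the supported interchange; BGEN/PLINK
  binary and VCF parsing are out of scope.
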