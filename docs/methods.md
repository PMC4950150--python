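# Methods

## Model and estimation

`repgwas` fits the repeated-measures animal model

    y = X b + Z g + Z p + e,
    g ~ N(0, σ_g² G),  p ~ N(0, σ_p² I_n),  e ~ N(0, σ_e² I_N),

where G is the VanRaden method-1 genomic relationship matrix
(`W W' / (2 Σ p_k(1−p_k))`, dosages mean-imputed per SNP and centered by
2p_k, allele frequencies taken from the sample). The polygenic term absorbs
confounding by relatedness; the permanent-environment term absorbs the
covariance among an individual's repeated measurements that is not genetic.
Dropping either term when the data carry its structure inflates association
test statistics.

Variance components are estimated by REML. The criterion is profiled:
σ_e² has a closed form given the ratios γ_g = σ_g²/σ_e², γ_p = σ_p²/σ_e²,
which are optimized on the log scale by L-BFGS-B from three starting points
(log-ratios (0,0), (−2,1), (1,−2)); convergence uses scipy's default
tolerances tightened to ftol 1e-12 / gtol 1e-7, and failure from all starts
raises an error carrying the evaluation trace. Ratios below ~2×10⁻⁶ are
reported as exactly 0 with a `boundary` flag. Every evaluation uses the
identity `H⁻¹ = I − Z(I + AD)⁻¹AZ'` (A = γ_gG + γ_pI, D = diag of per-
individual observation counts), so the cost is one n×n solve; when all
counts are equal the GRM eigendecomposition (cached on the
`RelationshipMatrix`) diagonalizes everything and an evaluation is O(n).
REML is used rather than hierarchical-likelihood estimation; for Gaussian
mixed models the two agree to well past the precision any of the
calibration checks require.

With a single observation per individual σ_p² is not separately
identifiable (only sums of components are); the fit succeeds and emits a
warning rather than failing, since the scan only needs V0.

## The scan

Stage 2 treats the fitted V0 as known and tests each SNP in
`y = Xb + x β + e`, `e ~ N(0, V0 σ²)`. The reference algorithm whitens with
`Λ^{-1/2}Γ'` from `V0 = ΓΛΓ'` (eigenvalues floored at 1e-8 of the maximum
before inversion), QR-factorizes the whitened fixed block once, and solves
per-SNP OLS on the residualized dosage column; σ² is re-estimated per SNP as
RSS/(N − rank), and β̂/SE is referred to the standard normal (at thousands of
observations the normal/t distinction is immaterial). A second code path
computes the identical quantities (x'V0⁻¹x, x'V0⁻¹y, ...) through the
low-rank structure of V0 with n×n solves only; the two paths agree to 1e-10
in the tests and both match a dense explicit-inverse GLS oracle, so the
choice (`method="auto"`: explicit rotation up to N=600, structured above) is
purely about memory and speed. Missing dosages are mean-imputed (2p̂);
zero-variance columns are flagged `monomorphic` and excluded from λ.

The genomic-control inflation factor is median-based by default
(median implied 1-df χ² over 0.4549); a regression (estlambda-style)
estimator is available. λ needs ≥10 finite p-values and is NaN for smaller
scans. No multiple-testing correction is applied by the scan itself; a
Bonferroni helper is provided.

## Synthetic data

`simulate_genotypes` draws per-SNP allele frequencies Uniform(maf_low,
maf_high) — default (0.05, 0.5), a post-QC spectrum — founders from
Hardy-Weinberg proportions, and full-sib families by Mendelian transmission
from two latent parents, giving sib-pair GRM entries near 0.5. This emulates
the family structure of a pedigreed wild population; it does not reproduce
linkage disequilibrium along chromosomes, multi-generation pedigrees, or
genotyping error, so calibration results transfer to real data only insofar
as those features matter.

`simulate_gaussian` composes QTL dosage effects, a polygenic draw
(eigendecomposition of G, negative eigenvalues clipped at zero with a
warning), permanent-environment and residual normals, and optional year
effects: i.i.d. N(0, σ_year²) per year label, added to every observation of
that year. Defaults are the study conditions: components (1, 1, 1), QTL
allele-substitution effect 0.5 (so homozygotes differ by 1.0), 10 years with
uniform year assignment avoiding within-individual repeats when possible.
The year count and assignment rule affect the magnitude, not the direction,
of the averages-model degradation. Year effects are *simulated* as random
draws but *fitted* as fixed effects in the scan — matching how field studies
treat year. Unbalanced designs draw counts Poisson(2), the unique standard
count law with mean = variance = 2; individuals drawing 0 are absent from
the replicate, which slightly raises the conditional mean — documented, not
corrected, since only the marginal moments are specified.

`simulate_binary` thresholds the Gaussian liability at τ expressed relative
to the mean liability of common-allele homozygotes, so τ = 0 gives those
individuals a 50/50 split regardless of where the QTL sits.

## Liability-threshold analytics

For a bi-allelic QTL with liability effect β_u per allele, threshold τ and
non-QTL liability variance σ_u², the penetrance is
Φ((g β_u − τ)/√σ_u²) and the estimand of a linear 0/1-response scan is the
HWE-weighted least-squares slope Cov(E[y|g], g)/Var(g), g ~ Binomial(2, p).
The observed-scale polygenic variance uses the first-order transform
φ(τ/√σ_u²)² σ_g²/σ_u² (= 0.053 at σ_g² = 1, σ_u² = 3, τ = 0). Two choices
matter and are validated in the test suite: σ_u² is the *non-QTL* liability
variance (3 at defaults — including the QTL variance does not reproduce the
expected values), and the allele frequency entering the "expected slope" is
the single effective p obtained by inverting the population fraction of
ones, which reproduces the reference values to within ±0.004 across the
whole threshold range. `solve_allele_freq` inverts the fraction by Brent
bracketing to 1e-10; the fraction is monotone in p for β_u ≠ 0.

## Averages baseline and comparison

The baseline averages each individual's observations, fits the
two-component model `V = Gσ_g² + Iσ_e²` on the means, and runs the same
rotated-GLS scan — the score-test-approximating analogue of an
`mmscore`-style analysis. Observation-count weighting is deliberately *not*
applied: the baseline mirrors the naive practice being critiqued.
`compare_methods` reports the percent increase in mean −log10 p at the
simulated QTL as the ratio of replicate means (recorded in the output
metadata, since mean-of-ratios is the other defensible choice) and the
correlation of −log10 p across all SNPs. `year_effect_sweep` pairs
replicates across year-variance shares with common random numbers: the same
sub-seed drives genotype-independent draws at every share, so only the year
effects scale and the trend is estimated within-replicate.

## Problem sizes and numerical choices

The packaged calibration runs use 300 related individuals (75 sib pairs +
150 unrelated) × 1500 SNPs × 4 observations for null calibration, type-I
error and binary-variance recovery, and the full 849-individual × 4-obs
configuration for effect recovery and power, where the power level is
n-dependent; replicate counts are 50–300 per quantity. These sizes keep a
complete recomputation within minutes on one CPU while leaving Monte-Carlo
standard errors well inside the tolerances checked.

Degenerate inputs: all-missing SNPs get NaN frequency and fall to the
call-rate filter; monomorphic SNPs return HWE p = 1 by convention; an
all-monomorphic panel makes the GRM denominator zero and errors; rank-
deficient fixed designs error naming the collinear columns; multi-allelic
VCF records are skipped with a logged count (the dosage model is
bi-allelic).

## Known limitations

- The per-SNP test re-estimates only the residual scale, not the variance
  ratios (the z1 full Wald and z2 score variants are not implemented); with
  very large SNP effects part of the signal is absorbed by the stage-1
  polygenic component, inflating σ̂_g² — the scan's detection behaviour is
  unaffected in the regimes tested.
- Binary traits are analysed on the observed 0/1 scale; for extreme
  proportions a genuinely binomial model should be preferred.
- No dominance, epistasis, genotype×year interaction, or sex-chromosome
  dosage models; imputation is per-SNP mean only.
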