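# Methods

This note records the statistical models implemented in `archpipe`, the
choices made where a design was genuinely open, and what the synthetic-data
tests do and do not establish.

## The liability-threshold model

All heritability arithmetic assumes a latent liability `L ~ N(0, 1)` with an
additive genetic component of variance `h²` (the heritability of liability);
disease occurs when `L > t = Φ⁻¹(1 − K)` for prevalence `K`.  Derived
quantities: `z = φ(t)`, mean liability of cases `i = z/K` (the selection
intensity) and of controls `i₂ = −z/(1 − K)`.  `K` defaults to 0.01, a
standard figure for a late-onset neurodegenerative disease.

**Recurrence risk.**  A relative with additive relationship `a` of an
affected proband has conditional liability mean `a h² i` and variance
`1 − a² h⁴ i (i − t)` (the truncated-normal variance-reduction
approximation), giving

    K_R = Φ̄( (t − a h² i) / √(1 − a² h⁴ i (i − t)) ),    λ_R = K_R / K.

The inverse map (λ → h²) is a monotone bisection/Brent solve on
`h² ∈ [0, 1+ε]`; roots above 1 are reported unclipped and flagged `">1"`.
An exact variant computes `K_R` from the bivariate-normal orthant with
liability correlation `a h²` (`exact=True`); the two agree to well under
0.01 on `h²` at the prevalences of interest.  The approximation is the
default because it reproduces published reference conversions at printed
precision; one published row (λ = 7.76 → 0.747) differs from both our
approximate and exact inversions (0.749 and 0.748) by ~0.002, a residual we
report rather than force.  The relationship coefficient for all reference
conversions is `a = 0.5` (first-degree).

**Maximum AUC.**  The best genetic score is the true genetic liability;
cases and controls then have normal score distributions with means `h²i`,
`h²i₂` and selection-reduced variances, so

    AUC_max = Φ( (i − i₂) h² / √( h²(1 − h² i(i − t)) + h²(1 − h² i₂(i₂ − t)) ) ).

A score explaining a fraction `v` of liability variance discriminates like a
trait with heritability `v`; `v_from_auc` inverts the same formula, and the
proportion of additive variance explained by a profile achieving a given AUC
is `v/h²`.

**Observed to liability scale.**  For a 0/1 phenotype measured in a sample
with case fraction `P` from a population with prevalence `K`,

    h²_liab = h²_obs · K(1−K)/z² · K(1−K)/(P(1−P)).

With `P = K` the second factor is 1 (the classical population-sample
transformation).

## Twin analysis

Probandwise concordance from ascertainment-stratified counts
(`C = (2d + s)/(2d + s + u)` for doubly/singly ascertained concordant and
discordant pairs) is converted to a tetrachoric correlation by solving
`P(L₁ > t, L₂ > t; r) = C·K` for `r`, and `h² = 2(r_MZ − r_DZ)` (the
Falconer contrast; shared-environment variance is assumed absent).
The bivariate-normal orthant probability is evaluated in closed form via
Owen's T function (machine precision); a brute-force two-dimensional
quadrature is kept in the test suite as an independent oracle.  Confidence
intervals come from a percentile bootstrap that resamples the three pair
categories per zygosity from independent multinomials (default 100,000
resamples); inside the bootstrap the concordance→correlation map uses a
dense monotone interpolation table whose error is orders of magnitude below
multinomial noise.  Point estimates above 1 are reported unclipped and
flagged; interval endpoints are reported both raw and clipped to [0, 1].

## Sporadic-case family simulation

The extended pedigree fixes exactly `c` children for every couple (default
`c = 3`), applied to the parental generation as well: the index has 2
parents, `c−1` siblings, `c` children, 4 grandparents, `2(c−1)`
aunts/uncles and `2c(c−1)` first cousins — 27 blood relatives at `c = 3`.
Spouses who marry in are founders with independent liabilities and are never
counted as relatives.  Liabilities are jointly normal with covariance
`h²A + (1−h²)I`, where `A` is the additive relationship matrix from the
standard recursive kinship computation.  Conditioning on an affected index
is exact: the index liability is drawn from the upper-truncated normal and
relatives from the conditional MVN, so no rejection sampling is needed even
at `K = 0.01`.

With `h² = 0.3`, `K = 0.01`, `c = 3`, the proportion of cases with no
affected relative in the full set is 64.3% — matching the published 64%.
The proportion with no affected parent or sibling is 90.3–90.4%, whereas
the published figure is 88%.  The parent/sibling figure is far more
sensitive to the assumed first-degree recurrence risk than the full-set
figure: the model-implied first-degree risk at `h² = 0.3` is `λ₁ ≈ 2.6`
(giving `(1 − λ₁K)⁴ ≈ 0.90`), while an empirical `λ₁ ≈ 3` — the value
familial studies report for this disease — gives `(1 − 0.03)⁴ ≈ 0.885`.
We report what the stated model produces.  Sensitivity to prevalence is
strong in both directions: at `K = 0.005` the full-set proportion rises to
~78%, at `K = 0.02` it falls to ~46%.

## Synthetic cohorts

Genotypes are biallelic SNPs in HWE with MAF drawn uniformly on
[0.05, 0.5] by default; causal standardized effects are normal, rescaled so
their squared sum is exactly `h²_l`; liability adds an `N(0, 1 − h²_l −
var_cov)` residual (plus optional sex/ancestry loadings), and cases are
ascertained at the requested case:control ratio.  During ascertainment only
causal genotype columns are drawn; non-causal columns are filled in for
retained individuals afterwards, which is distributionally identical and
keeps large-replicate studies fast.  Ages are drawn with cases older than
controls (≈62 ± 9 vs ≈48 ± 13 years) so covariate adjustment is
non-trivial; age and sex have no liability effect by default.  Platform
artifacts (differential missingness, symmetric genotype error),
case-label phenocopies, related pairs (probabilistic genotype copying with
copy probability equal to the target relationship), and twin-count
generation all operate on the same liability machinery.  Default
linkage equilibrium; genomic positions are synthetic and used only for
region counting.

What these cohorts do **not** emulate: realistic LD structure, imputation
uncertainty, rare-variant site-frequency spectra, X-chromosome dosages,
age-dependent penetrance, or population-specific MAF divergence beyond a
single latent ancestry scalar.  Passing tests establish the correctness and
calibration of the estimators under the generating model, not robustness to
these real-data features.

## Association scan and QC

Per-SNP QC: call rate (default ≥ 0.95), MAF floor (default 0.001 — panels
may carry rare large-effect custom variants, so a 1% floor would be wrong),
and the exact conditional Hardy-Weinberg test (Wigginton-style recurrence;
`p = 1` for monomorphic sites; computed in controls when both classes are
present).  Association is a per-SNP logistic regression on minor-allele
count plus covariates, tested by the likelihood-ratio statistic against the
covariate-only null (1 df), complete cases per SNP.  Quasi-separation
triggers a Firth (Jeffreys-prior) penalized fallback, flagged in the
output.  Ancestry components are classical MDS of the allele-sharing
distance `d = mean(|g_u − g_v|)/2`; genomic control is the median implied
χ²₁ over its null median (0.4549).  Trend-test power uses the
score-statistic non-centrality with case genotype frequencies obtained by
exponential tilting of the HWE control frequencies.

## GREML

GRM entries are `(1/m) Σ (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i))` with
per-SNP mean imputation of missing dosages and monomorphic SNPs excluded.
REML for `Var(y) = σ²_g·GRM + σ²_e·I` is computed in the GRM eigenbasis
(one `O(n³)` eigendecomposition, then `O(n p²)` per iteration):
average-information updates with an EM fallback whenever an AI step leaves
the admissible region, components floored at a small positive value,
convergence at `|Δ log L| < 1e-6`.  Standard errors come from the inverse
AI matrix at the optimum with the delta method for `h²_obs = σ²_g/(σ²_g +
σ²_e)`; the liability-scale CI is the linear transform of the
observed-scale CI (the transform is linear in `h²_obs`).

Relatedness pruning greedily removes the highest-degree sample (ties by
id) until no off-diagonal exceeds the threshold.  The production
convention of 0.025 is the `prune_related` default, but it presumes the
GRM noise floor of genome-wide panels (`sd ≈ 1/√m`, m in the hundreds of
thousands).  At the simulated panel sizes used here (m ≤ ~10⁴,
noise ≥ 0.01) an 0.025 cutoff removes most of an unrelated cohort, so the
pipeline configuration defaults to 0.2 — several sampling SDs — which
still isolates injected true relatives (a ≥ 0.25) reliably.

Dense REML is `O(n³)`; the pipeline caps GREML at n = 4000 by
configuration.  Parameter recovery is verified at n = 2000 (1 case : 4
controls), m = 5000, `h²_l = 0.3`, `K = 0.05` over 100 replicates:
95% CI coverage ≥ 90% and |mean bias| < 0.03.

## Sparse risk prediction

The fit minimizes the summed negative log-likelihood plus
`λ₁‖β‖₁ + λ₂‖β‖₂²` with an unpenalized intercept, by cyclic coordinate
descent on IRLS quadratic approximations (active set, periodic full
passes) with an explicit KKT certificate on the true objective at exit
(tolerance 1e-6·n).  `λ₂` defaults to `1e-3·n`: small enough not to
distort selection, large enough to make the solution unique in the
presence of correlated columns.  Genotypes enter on the dosage scale
(unstandardized, uniform penalty); missing dosages are mean-imputed at
fit time and contribute `w_miss = β · (training mean dosage)` at score
time — the serialized per-SNP missing-data weight.

`λ₁` is calibrated to an expected-false-positive bound: under the null a
SNP enters only when its score statistic `|Σ x_ij (y_i − ȳ)|` exceeds
`λ₁`, so `Σ_j 2Φ(−λ₁/σ_j) = E[FP]` with `σ_j² = ȳ(1−ȳ)Σ x_ij²`, solved
by bisection.  Using the uncentered second moment makes `σ_j`
conservative (an upper bound on the null score variance), so realized
selection falls below the bound — verified on 200 null-cohort fits per
grid point.  The default grid {0.05, 0.5, 5, 50, 500} spans
genome-wide-significant-only selection through deliberately permissive
models in geometric decades.  Bias-corrected refits drop `λ₁` on the
fixed support (ridge retained for stability).  Cross-validation folds are
dealt round-robin within sex × age-decile strata, separately for cases
and controls, so fold case:control ratios match the cohort's.

Model-implied ("predicted") AUC treats per-SNP score contributions as
independent, approximates case and control score distributions as normal
with moments from supplied genotype frequencies, and reports
`Φ(Δmean/√(var_case + var_ctrl))`.

## Covariate-adjusted AUC

The adjusted AUC is the probability that a random case outscores a random
control *from the same covariate stratum*: per-stratum Mann-Whitney
statistics combined with weights proportional to the stratum's
case × control pair count (strata lacking either class are excluded and
counted).  This weighting makes the statistic exactly the matched-pair
probability, which the tests verify by brute-force pair enumeration.
Default strata: sex × age decile × PC1 quintile, extended by fold or
platform where those apply; the reference analysis's exact scheme is not
published, so the stratum builder is configurable.  Difference tests use
a paired stratified bootstrap (cases and controls resampled within
strata, both scores evaluated on the same resample), one-sided
`p = (#{ΔAUC < 0} + ½#{ΔAUC = 0} + 1)/(B + 1)`, B = 1000 by default.

## Reproducibility and problem sizes

Every random operation takes an explicit seed; the pipeline derives one
child seed per stage from the master seed via `SeedSequence.spawn`, so
stage outputs are independently reproducible.  Test-suite problem sizes
are chosen for single-CPU desk-scale runs: the largest simulations are the
GREML recovery study (100 × n = 2000, m = 5000) and the 200,000-family
sporadic-case computation; everything else runs in seconds.  Quantities
that depend on real cohorts (specific SNP associations, a cohort's
heritability point estimate, external-validation AUC values on real
panels) are out of scope by construction: the pipeline demonstrates the
estimators' calibration on generated data instead.
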