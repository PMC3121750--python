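# archpipe

Quantitative genetic-architecture analysis for case-control traits:
liability-threshold conversions, twin and family heritability, GREML
variance components with the case-control liability transform, sparse
(elastic-net) polygenic risk prediction with expected-false-positive
calibration, and covariate-adjusted AUC evaluation — all exercisable end
to end on a built-in synthetic cohort generator, so no individual-level
genotype data is required.

## Who this is for

Statistical geneticists and epidemiologists who want a tested, desk-scale
implementation of the standard machinery for dissecting a dichotomous
trait's genetic architecture — e.g. a late-onset disease with prevalence
around 1% — and a simulation harness for checking that each estimator is
calibrated before pointing it at real data.

## The models

**Liability threshold.**  A latent liability `L ~ N(0,1)` with additive
genetic variance `h²`; disease iff `L > t = Φ⁻¹(1−K)` for prevalence `K`.
This single model links:

- the recurrence-risk ratio `λ_R` in relatives of affected probands to
  `h²` (via the truncated-normal approximation to the conditional risk);
- `h²` to the maximum AUC any genetic predictor can achieve,
  `AUC_max = Φ((i−i₂)h²/√(h²(1−h²i(i−t)) + h²(1−h²i₂(i₂−t))))`;
- an observed AUC to the fraction `v` of liability variance a score
  explains, and `v/h²` to the fraction of the additive variance captured;
- observed-scale (0/1) heritability to the liability scale,
  `h²_l = h²_obs · K(1−K)/z² · K(1−K)/(P(1−P))`.

**Twins.**  Probandwise concordance → tetrachoric correlation (bivariate-
normal orthant solve, Owen's T) → Falconer `h² = 2(r_MZ − r_DZ)`, with a
multinomial bootstrap over ascertainment-stratified pair counts.

**Families.**  Joint MVN liabilities over an extended pedigree
(`cov = h²A + (1−h²)I`), exact conditioning on an affected index, to
compute the expected proportion of "sporadic" cases.

**GREML.**  SNP-derived genetic relationship matrix, greedy relatedness
pruning, single-component AI-REML (eigenbasis implementation with EM
fallback), and the case-control liability transform.

**Risk prediction.**  Elastic-net logistic regression (coordinate descent
with KKT certificates), an L1 weight calibrated to a bound on the
expected number of null SNPs selected, bias-corrected refits, missing-data
score weights, matched cross-validation folds, and stratified
(covariate-adjusted) AUC with paired bootstrap difference tests.

## Worked example

```python
>>> from archpipe.liability import (h2_from_relative_risk,
...     max_auc_from_h2, prop_additive_explained)
>>> h2_from_relative_risk(3.0, "first", K=0.01)   # sibling/offspring risk ratio 3
0.35451750253182324
>>> max_auc_from_h2(0.272, K=0.01)                # ceiling for a h2=0.272 trait
0.8566275169696576
>>> prop_additive_explained(0.6, 0.272, K=0.01)   # an AUC-0.6 profile captures...
0.0645650739675065
```

Reading: a first-degree recurrence-risk ratio of 3.0 at 1% prevalence
implies a liability heritability of ≈0.35; a trait with `h² = 0.272` caps
any genetic predictor at AUC ≈ 0.857; and a risk score achieving AUC 0.6
for that trait explains ≈6.5% of its additive genetic variance.

The same numbers are in the conversion table the full pipeline writes:

```bash
archpipe run --out run1           # simulate → QC → assoc → GREML → risk → AUC
archpipe family-sim --h2 0.3 --K 0.01 --children 3 --n 200000 --seed 1
```

The `family-sim` command prints the proportion of affected individuals
with no affected relative (≈0.64 with the full parent/child/sibling/
grandparent/aunt-uncle/cousin set at these parameters) — the quantitative
reason a highly polygenic rare disease still presents mostly sporadically.

Other entry points: `archpipe liability`, `twin-h2`, `simulate`, `assoc`,
`greml`, `fit-risk`, `score`, `eval-auc`, `fixtures`.  See
`docs/methods.md` for the models, defaults and their rationale.

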