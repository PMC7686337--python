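# Methods

`sarc1066` implements a multi-site sarcopenia / sarcopenic-obesity analysis
of the kind used in cross-national ageing cohorts of adults ≥ 65, where body
composition is not measured directly but predicted from anthropometry, case
status is defined by within-cohort quintile cut-offs, and per-site estimates
are combined by fixed-effects meta-analysis. This note records the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## 1. Body composition

Per participant, from weight (kg), height (m), age (years), sex
(female = 0, male = 1) and a site-level ethnicity label:

* BMI = weight / height²
* %BF = 1.20·BMI + 0.23·age − 10.8·sex − 5.4
  (a published adult prediction equation, validated across populations)
* ASM = 0.244·weight + 7.80·height + 6.6·sex − 0.098·age + race − 3.3
  (a published anthropometric limb-muscle equation; `race` is an additive
  constant: 0 for White/Hispanic, −1.2 for Asian, +1.4 for Black)
* SMI = ASM / BMI
* gait speed = 10 m / walk time (s)

Derived values outside physiologic bands (%BF ∉ [3, 75], ASM ∉ [0, 60] kg)
are flagged but never clipped or dropped: the quintile machinery must see
exactly what the equations produce, and the analysis plan states no
trimming. The secondary literature disagrees on the sign of the Asian
constant (±1.2); the constant is site-level and therefore cancels out of
every within-site×sex quintile cut-off, so case ascertainment is invariant
to the choice — only absolute ASM/SMI levels shift. The mapping is config.

## 2. Case definitions

All three ingredients are empirical quintiles with an **inclusive**
boundary ("lowest quintile" includes its boundary value; ties therefore
behave predictably, and a degenerate all-equal stratum flags everyone):

| flag | variable | stratification | level |
|---|---|---|---|
| low SMM | SMI | site × sex | 20th percentile (≤) |
| slow gait | gait speed | sex × age band × height band, pooled over sites | 20th percentile (≤) |
| high %BF | %BF | sex, pooled over sites | 80th percentile (≥) |

sarcopenia = low SMM ∧ slow gait; sarcopenic obesity = sarcopenia ∧ high
%BF. Any missing ingredient makes dependent flags missing. Cut-offs are
site-specific **only** for SMI (body composition differs across
populations); gait and %BF cut-offs pool sites, with a per-site option in
config. Age bands are 65–69 / 70–74 / 75–79 / 80+; height bands are
within-sex tertiles of the pooled sample. Neither grid is dictated by the
analysis plan this mirrors (the source is silent); both are config-exposed.
Stratifying gait on speed or on walk time with the reversed tail yields
identical flags (speed = 10/time is strictly decreasing).

The quantile estimator is linear interpolation between order statistics
(type 7, the numpy/R default), config-exposed because Stata's default
differs; downstream tolerances absorb the difference at realistic n.

## 3. Prevalence

Crude per-site prevalence over records with a computable flag, with Wald
95% intervals p ± 1.96·√(p(1−p)/n) clipped to [0, 1]. Wald is the default
because it is the interval form that round-trips the published per-site
prevalence table from its printed prevalences and denominators; Wilson and
Clopper–Pearson are available behind `method=` for real use (Wald collapses
at boundary prevalences, which is warned about). Under imputation, the
per-imputation proportions and Wald variances are pooled by Rubin's rules
on the proportion scale.

## 4. Missing weight and multiple imputation

Weight is the only imputed variable (mirroring an analysis in which two
sites had substantial weight missingness and everything else was treated
complete-case). The imputation is *proper* normal-model regression:
among complete cases, weight is regressed on age, height, sex, education,
marital status, assets, physical activity, alcohol, smoking, walk time and
the four disease flags; for each of m = 50 (default) imputations the
residual variance is drawn from its scaled inverse-χ² posterior, the
coefficients from their conditional normal, and each missing weight from
the predictive normal. Draws are never truncated; implausible values
(< 25 or > 250 kg) are counted in diagnostics. Records missing an auxiliary
are left unimputed and reported. Rubin's rules: T = W + (1 + 1/m)·B,
df = (m−1)(1 + W/((1+1/m)B))², normal interval when B = 0.

Pipeline ordering: quintile cut-offs and flags are recomputed **within each
completed dataset** (default), the per-dataset estimates pooled afterward;
deriving cut-offs once from complete cases is available via
`cutoff_scope="complete_case"`. The source analysis does not state its
ordering; per-dataset is the choice that lets imputation uncertainty
propagate into case ascertainment. The imputation trigger is a site-level
missingness threshold (default 10%) with an explicit site-list override,
generalising the "impute these two sites" decision.

## 5. Association models

* Linear: OLS of SMI per site × gender (gender-stratified because SMI is
  not normal pooled) on age (years), education (ref none), marital (ref
  never), assets (0–7 count, linear), %BF, activity (ref low), alcohol
  (ref none/heavy), smoking (ref never), impairments (ref none), adjusted
  for dementia, depression, diabetes, stroke.
* Logistic: ML fit of sarcopenia / sarcopenic obesity per site on the same
  terms plus sex (ref female); %BF is excluded from the sarcopenic-obesity
  model, whose case definition already conditions on high %BF.

Rank-deficient (empty-category) terms are dropped with a warning and
recorded. Quasi-complete separation — an indicator level with zero cases or
zero non-cases — is detected before fitting; the offending term is set
aside and reported with infinite SE (keeping it out of every pool) while
the rest of the model is fitted. Residually unstable terms (|coef| > 12 or
SE > 50 on the log-odds scale) are likewise per-term excluded.
Non-convergence (Newton, tol 1e-8, 200 iterations) flags the whole fit and
excludes the site from pooling for that outcome, with a log entry. Sites
need ≥ 10 cases and non-cases (config) for a logistic fit.

Under imputation, each completed dataset is fitted and every term pooled by
Rubin's rules before meta-analysis.

## 6. Meta-analysis

Fixed-effects inverse-variance pooling across sites: w = 1/se²,
pooled = Σwθ/Σw, se = (Σw)^(−1/2). Logistic terms are pooled on the
log-odds scale and reported exponentiated (ORs are never averaged
directly). Heterogeneity: Cochran's Q, Higgins I² = max(0, 100(Q−(k−1))/Q)
with χ²(k−1) p-value; I² < 50% low, 50–75% moderate, ≥ 75% high. I² is
floored at zero; no small-k corrections. Flagged site fits are excluded
from the pool and logged (the mirrored analysis is silent on this; the
exclusion rule is config in spirit and recorded per run).

## 7. The synthetic cohort generator

The restricted survey data cannot be redistributed, so every downstream
stage is exercised on synthetic cohorts with *known, recoverable* ground
truth. Three design problems had to be solved jointly.

**(a) Exact linear truth for SMI.** The linear-model recovery tests need
the embedded %BF-on-SMI slope to be the exact estimand of the fitted OLS.
The generator therefore draws %BF first (per-sex normal, truncated in BMI
space so the %BF↔BMI↔age↔sex quadruple stays equation-consistent), builds a
structural SMI = site/sex intercept + b_age(age−75) + b_pbf(%BF−36) +
b_assets(assets−5) + category shifts + N(0, σ), and then *solves* the
body-composition system for height (a quadratic with one positive root) and
weight (= BMI·height²). Derived SMI downstream reproduces the structural
value to rounding (heights to 0.1 mm, weights to 10 g), so OLS on the true
covariates is unbiased by construction. Heights (≈ 1.51 ± 0.06 m women,
≈ 1.61 ± 0.07 m men) and weights (≈ 45–90 kg) emerge in realistic ranges.
The price is that height is almost a deterministic function of SMI given
%BF — see (c).

**(b) Exact logistic truth for sarcopenia.** Case status must *emerge from
the pipeline's own quintile cut-offs* (so the real code path is tested),
yet the male log-OR must be a well-defined estimand. The generator uses a
propensity-anchored rank coupling: an explicit logistic propensity
π(X) = expit(site intercept + θ_male·male + θ_age(age−75) + θ_pbf(%BF−36) +
θ_assets(assets−5)) decides joint tail membership. After SMI is realised
and the low-SMI flag determined by the empirical cut-off, a person in the
low tail is designated slow-gait with probability π(X)/P(low|X) (the
conditional that makes P(low ∧ slow | X) = π(X) exactly, with
P(low|X) = Φ((cutoff − μ(X))/σ) analytic under the structural model);
persons outside the low tail fill the remaining slow mass uniformly per
gait stratum to the 20% target. Walk speed is then assigned per gait
stratum as a lognormal quantile function of the person's designated rank
position, with the stratum median following a linear predictor in age,
height and sex — so speed still falls with age and rises with height on
average. Where π exceeds its feasibility envelope it is clipped; clip
fractions are reported in the provenance JSON and are ≈ 0.04% at defaults.

**(c) Feasibility.** Because sarcopenia ⊆ each 20% tail, the mean
propensity cannot exceed 0.2 within any gait stratum, and the structural
inversion concentrates low-SMI mass in the shortest height tertile. The
default propensity intercepts (−3.1 … −3.55) are set inside this envelope,
giving site sarcopenia prevalences of ≈ 4–8% — deliberately below the
12–25% a real multi-site cohort shows. The discrepancy is structural, not a
bug: published age-specific case distributions imply P(sarcopenia | 80+) up
to ≈ 0.34, which is arithmetically incompatible with 20% slow-gait tails
stratified on the age bands this pipeline uses; the mirrored analysis never
states its gait grid. The generator honours the constraint its own pipeline
imposes. Recovery of *effects* (the tests' purpose) is unaffected: across
100 seeds at 9 × 5,000, the pooled male OR averages 2.78 against an
embedded 2.80 and its 95% CI covers the truth in ≥ 90 seeds.

Other emulated features: age bands with a shifted-exponential 80+ tail,
site-specific sex splits and covariate prevalences in the ranges of the
published descriptive table, a single latent SES factor coupling education
and assets, disease flags as independent Bernoullis, and a logistic MAR
weight-missingness mechanism (site rate plus age/sex/height slopes)
concentrated in two sites (defaults 30% and 25%). Not emulated: survey
response/attrition, within-site covariate correlation beyond the SES
factor, measurement error in anthropometry, and real between-site effect
heterogeneity (truths are homogeneous so that I² calibration can be
tested). Passing tests therefore demonstrate correctness of the machinery
and honest uncertainty propagation, not that real data would show these
prevalences or effect sizes.

Default per-site sample sizes are the analysable sizes implied by the
published age-band counts (410–1,913); recovery simulations use 5,000/site
and the imputation simulations 2,000, sizes at which the checked
asymptotics hold comfortably.

## 8. Numerical conventions and degenerate inputs

* Sex coding female = 0 / male = 1 everywhere (required by both equations).
* Reference category = first listed category of each enumeration.
* Quantiles: type 7; flags: inclusive boundaries.
* Wald CIs clipped to [0, 1]; boundary prevalences warn.
* Logistic convergence: Newton, log-likelihood tol 1e-8, max 200
  iterations; non-convergence is a flagged result, never a silent estimate.
* Determinism: every stochastic step flows from a single integer seed
  through `numpy.random.default_rng`; identical config + seed reproduces
  byte-identical artifacts (no timestamps in outputs).
* Validation is total: every input row is accepted or appears once in the
  rejects report; generator output is itself validated and any rejection is
  a hard error.

## 9. Known limitations

* Only the two cited prediction equations; no DXA/BIA calibrations, no
  grip-strength or consensus (EWGSOP/FNIH) definitions.
* No survey weights, age standardisation, random-effects pooling or
  publication-bias diagnostics.
* The generator's low prevalence relative to real cohorts (see 7c).
* Chained-equations multivariate imputation is out of scope; only weight
  is imputed, and records missing an auxiliary stay unimputed.
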