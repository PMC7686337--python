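# sarc1066

A tested, reusable pipeline for multi-site sarcopenia and sarcopenic-obesity
analysis in older-adult cohorts (≥ 65 years) where body composition is
predicted from anthropometry rather than measured: equation-based %BF and
skeletal-muscle estimation, stratified quintile case definitions, multiple
imputation of missing weight, per-site regression models, and fixed-effects
meta-analytic pooling with Higgins I² — plus a synthetic multi-site cohort
generator with known, recoverable ground truth, so the whole pipeline is
testable without restricted survey data.

Intended users: epidemiologists and biostatisticians running 10/66-style
cross-national ageing analyses, and methodologists who want a transparent
reference implementation of this case-ascertainment + pooling workflow.

## The model

Per participant, with sex coded female = 0 / male = 1:

```
BMI  = weight / height²                      (kg/m²)
%BF  = 1.20·BMI + 0.23·age − 10.8·sex − 5.4
ASM  = 0.244·weight + 7.80·height + 6.6·sex − 0.098·age + race − 3.3   (kg)
SMI  = ASM / BMI
gait speed = 10 m / walk time                (m/s)
```

Case definitions are empirical quintiles with inclusive boundaries:
**low SMM** = SMI ≤ 20th percentile of its site × sex stratum; **slow
gait** = speed ≤ 20th percentile of its sex × age-band × height-band
stratum (pooled over sites); **high %BF** = %BF ≥ sex-specific 80th
percentile. **Sarcopenia** = low SMM ∧ slow gait; **sarcopenic obesity** =
sarcopenia ∧ high %BF.

Per-site prevalences get Wald 95% CIs, p ± 1.96·√(p(1−p)/n). Missing
weight is multiply imputed (proper normal-model regression, m = 50 default)
and combined by Rubin's rules, T = W + (1 + 1/m)·B. Per-site OLS (SMI, per
gender) and logistic (case flags) estimates are pooled by fixed-effects
inverse variance, w_i = 1/se_i², with Cochran's Q and
I² = max(0, 100·(Q − (k−1))/Q). See `docs/methods.md` for defaults,
assumptions and limitations.

## Worked example

```python
import numpy as np
import sarc1066 as s

# nine synthetic sites, 2000 participants each, complete weight
profiles = s.default_profiles(n=2000, weight_missing=False)
table = s.simulate_cohort(profiles, seed=1)

eth = {p.site: p.ethnicity for p in profiles}
derived = s.add_derived(table.df, eth)        # BMI, %BF, ASM, SMI, gait speed
derived, _ = s.add_strata(derived)            # age bands, height tertiles
cutoffs = s.derive_all_cutoffs(derived)       # quintile thresholds
flags = s.flag_cases(derived, cutoffs)        # per-person case flags

prev = s.estimate_prevalence(flags, "peru_rural", "sarcopenia")
print(f"peru_rural sarcopenia: {100*prev.p:.1f}% "
      f"(95% CI {100*prev.ci_low:.1f}-{100*prev.ci_high:.1f}), n={prev.n}")

fits = [s.fit_logistic_case(flags, p.site, s.default_spec("sarcopenia"))
        for p in profiles]
pooled = s.build_pooled_tables([f for f in fits if f.ok])
row = pooled[pooled["term"] == "sex[male]"].iloc[0]
print(f"pooled male OR: {np.exp(row.estimate):.2f} "
      f"(95% CI {np.exp(row.ci_low):.2f}-{np.exp(row.ci_high):.2f}), "
      f"k={row.k} sites, I2={row.i2:.1f}% (p={row.q_pvalue:.3f})")
```

prints

```
peru_rural sarcopenia: 6.8% (95% CI 5.7-7.8), n=2000
pooled male OR: 2.77 (95% CI 2.18-3.51), k=7 sites, I2=0.0% (p=0.555)
```

The prevalence line is the crude Wald-interval estimate over the 2,000
records with computable flags at that site. The pooled line is the
fixed-effects inverse-variance combination of the per-site male-vs-female
log-odds ratios for sarcopenia (two small sites were excluded by the
convergence guard at this sample size): the generator embeds a male log-OR
of log 2.8, and the pooled estimate recovers it with no detectable
between-site heterogeneity — exactly what a homogeneous-truth simulation
should show.

The same analysis is one command from a shell:

```sh
sarc1066 run-all --seed 1 --out results/
```

which writes the cohort, derived table, cut-offs, flags, per-site
prevalences, site fits, pooled tables and a provenance JSON that reproduces
the run byte-for-byte.

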