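# comoscore

Comorbidity indices from ICD-10 hospital-discharge diagnoses — Charlson
(CCI), Elixhauser (ECI) and van Walraven (WCI) — and a head-to-head
evaluation of the three as predictors of in-hospital death.

## The problem

Administrative discharge registries (in Spain, the Minimum Basic Data Set,
MBDS: one main diagnosis plus up to 19 secondary ICD-10 diagnoses per
hospitalization) are the workhorse of risk-adjusted outcome studies, but the
adjustment depends on how comorbidity is summarized. Three summaries
dominate the literature, all computed from the Quan ICD-10 coding
algorithms:

- **CCI** — weighted sum over 17 Charlson categories,
  `CCI = Σ_k w_k x_k` with integer weights `w_k ∈ {1, 2, 3, 6}`;
- **ECI** — unweighted count of the 31 Elixhauser categories present,
  `ECI = Σ_k x_k`;
- **WCI** — van Walraven's mortality-derived weighting of the Elixhauser
  flags, `WCI = Σ_k v_k x_k` with `v_k ∈ {-7, …, 12}` (so WCI can be
  negative).

Severity hierarchies (metastatic cancer suppresses "solid tumor without
metastasis", complicated diabetes suppresses uncomplicated, severe liver
disease suppresses mild) keep each condition counted once.

The package scores every episode three ways, cuts each score into quartile
strata, quantifies how far the three instruments agree (Spearman's rho and
the absolute-agreement intraclass correlation ICC(A,1)), fits age-adjusted
logistic models for in-hospital death (`logit P(death) = β₀ + β₁·stratum +
β₂·1[age > median]`, with both ordinal and categorical stratum codings), and
compares the indices' discrimination by ROC AUC with DeLong's test for
paired AUC differences.

Because the national registry is access-restricted, the package ships a
synthetic cohort generator that emulates its structure — published category
prevalences, median age 72, ~4.47 % in-hospital mortality, death risk driven
by the weighted comorbidity burden — with a full latent truth table so every
pipeline stage can be validated exactly.

## Worked example

```python
from comoscore import ComorbidityMortality, GeneratorConfig, generate_cohort

cohort, truth = generate_cohort(GeneratorConfig(n_episodes=10_000, seed=42))
results = ComorbidityMortality(cohort).fit()
print(results.summary())
```

```
Comorbidity indices vs in-hospital mortality
============================================================
Episodes analyzed: 10000   deaths: 441 (4.41%)   median age: 72

Score medians (IQR):
  CCI  1 (0-3)
  ECI  2 (1-4)
  WCI  4 (0-10)

Agreement between strata (Spearman rho / ICC absolute):
  cci vs eci: rho=0.680 (moderate), ICC_A=0.660 [0.632, 0.686] (fair to good)
  cci vs wci: rho=0.669 (moderate), ICC_A=0.663 [0.652, 0.674] (fair to good)
  eci vs wci: rho=0.638 (moderate), ICC_A=0.613 [0.583, 0.641] (fair to good)

Discrimination (AUC, DeLong 95% CI):
  cci: AUC=0.731 [0.708, 0.754]
  eci: AUC=0.717 [0.693, 0.740]
  wci: AUC=0.774 [0.752, 0.797]
  ranking: wci > cci > eci
```

Reading the output: the three indices correlate only moderately — they are
*different* measurements of comorbidity, not interchangeable — and the
mortality-weighted WCI discriminates deaths best (here AUC 0.774, with the
DeLong tests against CCI and ECI both p < 1e-6), while all three sit in the
"acceptable" 0.70–0.80 band. The per-stratum odds ratios (in
`results.or_table`) rise monotonically from the reference stratum 1,
reaching OR ≈ 7–13 in stratum 4 depending on the index, with age above the
median roughly doubling the odds of death throughout.

`results.save_tables("out/")` writes every table (frequencies, strata
intervals, agreement, ORs, AUCs, DeLong, ROC points) as CSV plus a JSON run
manifest; `results.plot_roc()` draws the three ROC curves.

The same pipeline runs from the shell:

```bash
comoscore simulate sim/ --n 10000 --seed 42
comoscore run sim/episodes.csv --outdir results/
```

Real data are read from a wide CSV (`episode_id, age, sex, death,
length_of_stay, obstetric_flag, year, dx_main, dx_sec_01..dx_sec_19`) or a
long episode+diagnosis pair of CSVs; see `comoscore.io`.

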