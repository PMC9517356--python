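# Methods

## Scope

`comoscore` implements a complete comparison of three comorbidity indices
computed from ICD-10 discharge diagnoses — Charlson (CCI), Elixhauser (ECI)
and van Walraven (WCI) — as predictors of in-hospital death, together with
a synthetic discharge-registry generator that stands in for restricted
national data. It does not implement ICD-9 algorithms, Deyo/Romano/AHRQ map
variants, the age-adjusted Charlson variant, DRG/MDC grouping, calibration
analysis or survival modelling.

## Coding algorithms and maps

The packaged maps (`comoscore/data/*.csv`) transcribe the Quan et al.
(2005) ICD-10 coding algorithms: 17 Charlson categories with the original
Charlson (1987) weights (1/2/3/6) and 31 Elixhauser categories with the
van Walraven et al. (2009) in-hospital-mortality weights (−7 … 12). They
are plain editable CSVs so the transcription is reviewable; `load_map`
validates the structural invariants (category counts, non-empty normalized
prefixes, hierarchy labels) at load time.

Matching is by code family: a diagnosis, normalized to uppercase with dots
and whitespace removed, belongs to a category when any of the category's
prefixes is a leading substring (prefix `I50` captures `I500`–`I509`).
Severity hierarchies then demote the milder member of each pair
(complicated over uncomplicated diabetes, moderate/severe over mild liver
disease, metastatic cancer over non-metastatic malignancy) so no condition
is double counted. Hierarchy application is idempotent and its pairs are
mutually exclusive in every emitted profile.

The two hypertension rows of the Elixhauser scheme are kept separate (31
categories); both carry van Walraven's single hypertension weight (0). The
main diagnosis counts toward comorbidity by default — the classical
secondary-diagnoses-only reading is available via `include_main_dx=False`.

## Scores, quantiles and strata

- `CCI = Σ charlson_weight · flag` (integer ≥ 0)
- `ECI = Σ flag` (count, 0–31)
- `WCI = Σ vw_weight · flag` (integer, may be negative)

Summary quantiles (medians, IQRs) use the classical empirical convention of
mainstream statistical packages (ceil rule for non-integer `n·q`, average
of adjacent order statistics at integer `n·q`); linear interpolation is
available via `convention="linear"`.

Each index is cut into four quartile strata of its own score distribution.
The scores are small integers with heavy ties, so exact quarters are
impossible and tied scores must share one stratum. Empirical strata use the
**rank-midpoint rule**: a distinct score whose observations occupy
cumulative fractions `(F_lo, F_hi)` is assigned the quartile containing
`(F_lo + F_hi)/2`; a stratum emptied by a dominant tie group is closed up
by renumbering, which keeps the categorical logistic design full rank. This
rule reproduces the published strata layouts of all three indices
(e.g. van Walraven −14…−1 | 0…3 | 4…11 | 12…52), which no single
left- or right-closed threshold rule does. Explicitly supplied cutpoints
(e.g. transcribed from a published table) are applied verbatim under a
left-closed threshold rule `stratum = 1 + #{c : score ≥ c}`.

## Agreement

Both statistics are computed on the strata (1–4) by default, matching how
the indices are used downstream; raw-score vectors can be passed instead.

- **Spearman's rho**: Pearson correlation of mid-ranks (average ranks under
  ties), p two-sided from the t approximation on n−2 df (scipy). An exact
  check against a rank-then-Pearson oracle is part of the test suite.
- **ICC(A,1)**: two-way model, two fixed raters, single measurement,
  absolute agreement: `(MS_R − MS_E) / (MS_R + MS_E + (2/n)(MS_C − MS_E))`
  from the subject/rater/error mean squares. The 95% CI uses the
  McGraw & Wong F-based method; the p-value against ICC = 0 uses
  `F = MS_R/MS_E` on (n−1, (n−1)(k−1)) df. The implementation matches
  pingouin's ICC(A,1) to 1e-8 on random toys. The two-rater single-measures
  choice is forced by the pairwise design; exact agreement (y = x)
  degenerates the interval to the point estimate.

Qualitative labels follow the conventional verbal scales (rho: none / poor
/ fair / moderate / very strong / perfect; ICC, after Fleiss: poor < 0.40,
fair to good 0.41–0.75, excellent > 0.75). The scales leave gaps between
named bands; a gap value takes the nearer band's label, ties resolved
toward the stronger band.

## Mortality models and discrimination

Per index, two maximum-likelihood logistic fits (statsmodels, Newton
iterations, tolerance 1e-10, max 50 iterations), both adjusted for age
dichotomized at the cohort median (lower-middle convention for even n):

- *ordinal*: stratum 1–4 as an integer covariate → one "score (all
  strata)" OR per unit stratum;
- *categorical*: strata 2–4 as indicators vs stratum 1 → per-stratum ORs.

ORs are `exp(β)` with Wald 95% CIs `exp(β ± 1.96·SE)` from the inverse
observed information; the reference stratum is reported as OR ≡ 1 without
a CI. Coefficients above 15 in absolute value with a non-vanishing score
are treated as complete separation and raised as an error.

ROC curves sweep the distinct predictor values descending, grouping ties
into diagonal segments. The AUC is computed twice — trapezoidal area of the
curve and the Mann–Whitney statistic with half credit for ties — and the
two must agree to 1e-12 (an internal assertion). The default ROC predictor
is the fitted probability of the *ordinal* model (stratum + age), which is
a strictly monotone function of the stratum whenever the stratum effect is
positive, so raw-stratum AUC is recovered exactly when the age coefficient
is zero; `predictor_mode="raw_score"` scores episodes by the raw index
instead. AUC variances, covariances and the paired z-test use DeLong's
placement-value method (midrank formulation); the AUC CI is Wald on the AUC
scale with the DeLong SE. No multiple-testing correction is applied across
the three pairwise tests.

## Synthetic cohort generator

The generator emulates an adult general-hospital discharge population:

- **Comorbidity flags.** Each of the 31 Elixhauser categories plus the
  three Charlson-only categories (myocardial infarction, cerebrovascular
  disease, dementia) is drawn Bernoulli at its published prevalence
  (e.g. uncomplicated hypertension 36.34 %, CHF 12.94 %). Flags are coupled
  through an equicorrelated Gaussian copula, default correlation 0.15: real
  comorbidities co-occur, and under full independence the unweighted count
  (ECI) becomes an unrealistically poor proxy for the weighted burden —
  discrimination and inter-index agreement both fall well below what is
  observed in registry data. Setting the knob to 0 restores independent
  flags. Where a hierarchy links two categories the inferior is suppressed
  at draw time and its draw probability inflated by `1/(1 − p_superior)`,
  so post-hierarchy prevalences stay on target.
- **Codes.** Each drawn condition emits one ICD-10 code sampled uniformly
  from its own family, restricted to codes unambiguous within the
  Elixhauser scheme (Charlson-only conditions: unambiguous in Charlson and
  matching nothing in Elixhauser). Three-character prefixes are expanded
  with a digit so prefix matching is genuinely exercised. The main
  diagnosis and 0–3 filler secondaries come from a fixed list of acute
  codes matching no category. Consequently recovering flags from the
  emitted codes reproduces the latent truth exactly — a round-trip identity
  asserted over 10,000 episodes in the test suite.
- **Demographics.** Age from the mixture 0.32·N(48, 14²) + 0.68·N(77, 9²),
  rounded and clipped to [19, 105], targeting median 72 and IQR ≈ 56–80
  (the three quantiles are targeted, not enforced); male share 0.5479;
  length of stay log-normal with median 4 days and IQR ≈ 2–8.
- **Mortality.** Death is Bernoulli with
  `logit p = β₀ + 0.13·WCI + 0.85·1[age > 72]`. The slopes were fixed once
  from the magnitudes of published per-stratum odds ratios and an AUC
  target of ≈ 0.75 for the weighted index; the intercept is calibrated at
  generation time by bisection on a 200,000-draw latent sample so the
  marginal death rate hits 4.47 %. Because death is generated from the WCI
  linear predictor, the weighted index is the best possible predictor *by
  construction* — the qualitative headline the pipeline should recover —
  while ECI and CCI act as degraded proxies. Alternative generators keyed
  on ECI or CCI (`risk_index=`) exercise the comparison machinery without
  a favoured index.
- **Contamination.** Optional fractions of under-age and obstetric
  episodes (default 0) exist solely to test the adult/non-obstetric filter.

Identical config + seed yields a bitwise-identical cohort (seeds are
spawned deterministically for the calibration and cohort draws).

What the generator does **not** model: admission-type (MDC) composition,
readmission structure, dependence of length of stay on mortality, coding
noise (under-recording of chronic disease), or realistic pairwise
prevalence structure beyond the single equicorrelation knob. Passing tests
therefore demonstrate correctness of the *pipeline* under a favourable,
fully-specified data-generating process — not the clinical validity of any
index on real registry data.

## Problem sizes and numerical choices

The test suite validates scoring against naive-summation oracles (1,000
random profiles, exact integer equality), the mapping round trip at
n = 10,000, the ROC dual computation to 1e-12 on 100 random sets, DeLong
type-I error over 1,000 null replicates of n = 2,000 (rejection rate within
[0.03, 0.07] at α = 0.05), single-AUC variance against a 50,000-resample
bootstrap (within 10 %), logistic CI coverage over 200 replicates of
n = 10,000 (within [0.90, 0.99]), and the headline ordering over 20 seeds
of n = 50,000 cohorts. The acceptance script uses one n = 50,000 cohort.
These sizes keep the full suite around a minute while leaving Monte-Carlo
margins comfortably inside the asserted bands.

Degenerate inputs are defined errors, not silent results: empty cohorts,
one-class outcomes, all-identical scores, zero-variance rank vectors and
complete separation each raise a typed exception (`comoscore.exceptions`),
and the CLI maps validation errors to exit code 2, model/calibration errors
to exit code 3.

## Design choices that were genuinely open

- "Adults" is read as age ≥ 19 at admission (`min_age=19`); an
  inclusive-18 reading is one flag away.
- Obstetric exclusion travels as an explicit `obstetric_flag` column
  (admission-type semantics); `infer_obstetric_flag` sets it from ICD-10
  chapter O codes when no admission-type field exists.
- Episodes missing age, sex or death are dropped and reported, never
  imputed.
- The "all strata" OR and the per-stratum ORs come from two separate fits
  (ordinal and categorical), the only reading under which both can be
  reported for the same index.
- Strata, not raw scores, enter the agreement statistics and the default
  models; raw-score modes exist for both.
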