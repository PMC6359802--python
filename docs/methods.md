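# Methods

## The analysis

`prolifsig` implements a biomarker analysis for immune-checkpoint-inhibitor
(ICI)-treated non-small-cell lung cancer (NSCLC): whether the *proliferative
state of the tumor microenvironment* — summarized by a 10-gene signature —
stratifies response beyond the standard PD-L1 tumor proportion score (TPS).

The pipeline has five stages.

### 1. Cohort filtering and response classification

Patients carry RECIST v1.1 best response, survival from first ICI dose,
vital status and follow-up (all times in months). Classification:

* CR or PR → disease control (**DC**), at any survival duration. The
  12-month clause is read as binding stable disease only; a config flag
  (`dc_requires_12mo_for_cr_pr`) applies it to CR/PR as well.
* SD with ≥ 12 months survival → DC; SD with < 12 months → **NDC**.
* PD → NDC.
* Death within 90 days of first dose → excluded (rapid progression cannot
  be separated from poor performance status), regardless of response.
* Alive with < 90 days follow-up and no evaluable response → excluded.
* Otherwise-unevaluable responses (no target lesion, missing scans) carry
  a `not_evaluable` label: they stay in survival analyses but not in
  response statistics.

90 days is converted to months as 90 / 30.44 ≈ 2.957 when times are stored
in months; the comparison is strict (`<`), so death at exactly 90 days is
retained. Whether the 12-month SD window runs from first dose (assumed
here) or from response assessment is not decidable from the source data
conventions; the package measures it from first dose.

The train/test split holds out the single largest contributing
institution as the test set (lexicographic tie-break, with a warning).

### 2. Rank normalization

Raw targeted-panel expression is not comparable across batches; each gene
is therefore expressed as a 0–100 percentile rank within a fixed
**reference population** of tumors (the emulated reference has 167
multi-tumor samples, mirroring the assay's production reference). Ties use
the midpoint convention, `rank = 100·(#below + ½·#equal)/n_ref`, so a
sample identical to a reference member receives that member's mid-rank.
Ranks are kept continuous; rounding to integers would create artifacts at
the tertile boundaries.

A **signature score** is the arithmetic mean of member-gene ranks. Scores
are discretized by fixed cuts: low < 33, medium 33–66 (both boundaries
inclusive), high > 66.

### 3. Function screen

The panel's 394 genes are divided into 41 immune-function categories.
For each category, every evaluable patient is scored, scores are cut into
tertiles, and the DC rate is compared between each tertile pair
(low/medium, medium/high, low/high) by a 2×2 chi-square with Yates
continuity correction; the three p-values are Holm-adjusted within the
category. A category with an empty tertile lacks dynamic range in the
study population and is excluded rather than tested. The report is the
full table ranked by minimum adjusted p — the α = 0.05 line is a
reporting aid, not a hard filter, since borderline categories are of
interest in an exploratory screen.

Two deliberate conventions:

* **Holm family.** The default family is the 3 comparisons within one
  category; `holm_family="global"` adjusts across all 123 tests at once.
* **Scale of the cuts.** By default the 33/66 cuts apply to the raw mean
  of member-gene ranks. Passing `reference=` to `screen_categories`
  instead re-ranks each category score against the reference population's
  own score distribution first (the convention proliferation status
  uses). The default keeps the screen on the scale the category scores
  are reported on; for the tightly co-regulated proliferation signature
  the two conventions agree for ~98.5% of patients.

### 4. Stratification

* **Proliferation status**: the patient's 10-gene mean rank is re-ranked
  against the distribution of the same score in the reference population,
  then cut at 33/66 → poorly / moderately / highly proliferative. A
  `rerank=False` switch applies the cuts to the raw mean instead.
* **PD-L1**: TPS < 1% negative, 1–49% weakly positive, ≥ 50% strongly
  positive. Missing TPS excludes a patient from PD-L1 analyses only.
* **Cold tumors**: CD8 transcript rank (mean of CD8A and CD8B reference
  ranks; configurable to CD8A alone) below 15 (strict, arbitrary cut) or
  below 33 (lower tertile).
* **Single-gene accuracy**: each signature gene, and the 10-gene mean,
  is turned into a classifier — *moderately* predicts DC, anything else
  predicts NDC — and tabulated against observed DC/NDC;
  accuracy = (TP+TN)/n. The moderately→DC rule is a stated convention
  (see “Published rows that do not reproduce”).

### 5. Outcome statistics

* **Contingency**: DC rates between two strata by the same
  Yates-corrected chi-square; k-group questions are decomposed into the
  stated pairs.
* **Survival**: Kaplan–Meier product-limit curves truncated at a 5-year
  horizon (later observations administratively censored at 60 months);
  ties resolve events-before-censorings; the median is the earliest time
  with S(t) ≤ 0.5 (infinite if never reached; confidence intervals are
  reporting-only). Two-group comparisons use the standard log-rank
  chi-square (df = 1).
* **Multivariate model**: binomial logistic regression of DC on the
  moderately-proliferative indicator, PD-L1 positivity (TPS ≥ 1%, one
  degree of freedom), histology, race, sex and age category, fitted by
  IRLS (statsmodels GLM; max 100 iterations, deviance tolerance 1e-10),
  treatment coding against the first-sorted level. A sequential (Type-I)
  analysis-of-deviance table adds terms in that fixed order; each term's
  deviance drop is tested against χ² at the term's df. Coefficients
  beyond ±15 on the logit scale flag (quasi-)complete separation — the
  fit is reported with a divergence warning rather than suppressed,
  since sparse race/age cells make this pathology expected at n ≈ 110.

## The synthetic-study generator

The generator (`prolifsig.simulate`) produces a reference population and
an ICI-treated cohort with the statistical structure the analysis
assumes, so that every stage is testable end-to-end without restricted
patient-level data. Defaults are the emulated study conditions:

| parameter | default | why |
|---|---|---|
| reference size | 167 | size of the assay's multi-tumor reference |
| cohort size | 120 survival-eligible | emulated cohort size |
| panel | 394 genes, 41 categories | panel design |
| latent loading | 0.8 | shared proliferation axis on the 10 signature genes |
| gene noise SD | 0.10 (log scale) | signature genes are tightly co-regulated, so the signature score spans the full rank scale — as the observed 22.5/38.3/39.2% tertile spread implies |
| tertile targets | 22.5 / 38.3 / 39.2 % | observed poorly/moderately/highly prevalence |
| TPS prevalence | 26.7% strong, 46.7% any-positive | observed PD-L1 distribution |
| strong-positive logit shift for moderately | +0.97 | reproduces the observed enrichment (38.6% vs 19.3% strong positivity) while the base rate is solved so the marginal stays on target |
| DC probabilities | per (proliferation × strong-PD-L1) cell, e.g. 0.588 / 0.444 for moderately ± strong | observed stratum DC rates |
| survival medians | 14.6 / 12.6 / 11.5 / 7.6 months | observed per-stratum medians |
| alive fraction | 0.50 | observed censoring |
| not-evaluable fraction | 10/120 | observed disposition |
| early-death fraction | 0.06 | so the 90-day exclusion is exercised, not bypassed |
| cold fraction (< 15 rank) | 0.50 | the cohort is cold-heavy relative to the multi-tumor reference |

Mechanics and the reasoning behind the non-obvious choices:

* **Expression** is log-normal: `log x = baseline + loading·latent + ε`.
  Only the 10 signature genes load on the latent axis; all other genes'
  ranks are exactly uniform regardless of noise level (rank is monotone
  in value), so the noise SD matters only through the within-signature
  correlation.
* **Patient latent distribution** is normal with mean/SD solved from the
  tertile targets via the approximation rank ≈ 100·Φ(latent). The
  residual inaccuracy is 1–3 points; each study's single finite reference
  adds ±3.5 points of tertile-cut wiggle that is systematic within the
  study — tests therefore check prevalence targets pooled over
  independent studies.
* **TPS** is a zero-inflated mixture: point mass at 0, uniform on
  [1, 50) for weak positives, uniform on [50, 100] for strong. The base
  strong-positive weight is solved (Brent root-find) so the marginal
  prevalence hits its target given the realized moderately fraction and
  the logit shift.
* **Responses are drawn on the measured strata.** The generator runs the
  actual ranking/stratification pipeline on its own expression and draws
  DC per (proliferation, strong-PD-L1) cell — so recovery tests measure
  the estimator, not a private labelling rule. Best response is kept
  consistent with the drawn label and observed time (a DC patient
  observed under 12 months is CR/PR, never SD; an NDC-SD patient is only
  generated when observed time is under 12 months).
* **Survival** is a 90-day-shifted exponential per stratum:
  `T = c + Exp(ln 2/(median − c))` with c = 2.957 months. The printed
  medians describe the post-exclusion cohort, and by memorylessness a
  plain exponential cannot both carry that median and respect the
  inclusion window; the shift is the minimal model that does. Censoring
  times are uniform on [c, c_max] with c_max solved so the expected alive
  fraction matches the target. Excluded early deaths are generated
  separately, uniform inside the window.
* **Catalog**: the three categories with published membership
  (proliferation, antigen processing, dendritic cell) ship as a packaged
  GMT fixture; the other 38 are synthetic (named
  `synthetic_function_NN`) and partition the remaining panel genes —
  "divided into 41 categories" implies a partition — giving realistic
  sizes of ~7–13 genes. CD8A/CD8B are panel members used for the
  cold-tumor rank, not a screened category.
* **Determinism**: one integer-seeded numpy Generator drives everything;
  a seed reproduces byte-identical outputs.

### What the generator does and does not emulate

It reproduces rank-scale marginals, stratum prevalences, stratum-wise DC
rates and survival medians, censoring, the disposition funnel and the
institution skew. It does **not** emulate: correlated expression within
the null categories (real co-functional genes correlate; here only the
proliferation axis does), batch effects or assay noise heterogeneity,
covariate–outcome associations other than through proliferation and
PD-L1 (histology, race, sex and age are drawn independently), missing
TPS, or any upstream sequencing artifacts. Passing recovery tests
therefore shows the estimators are correct for data meeting the model's
assumptions — not that real cohorts meet them.

## Published rows that do not reproduce

Recomputing every published contingency row from its own printed counts
validates most of the table exactly (seven p-values to the printed
precision, and the deviance table to all printed digits). Four published
results diverge from their own counts and are deliberately **documented,
never asserted**:

* the strongly-positive vs not-strongly-positive DC comparison prints
  p = 0.0009, but its counts (16/32 vs 19/78) recompute to p ≈ 0.0165;
* the cold (< 33) row prints p = 0.3298, but 5/10 vs 0/11 recomputes to
  p ≈ 0.0297;
* the moderately-vs-highly and moderately-vs-poorly p-values
  (0.0146 / 0.0113) appear transposed: recomputation gives 0.0113 for
  the highly and 0.0146 for the poorly comparison;
* the published 71.8% accuracy of the 10-gene mean cannot be
  reconstructed under the moderately→DC rule — the same counts give
  (22+53)/110 = 68.2% — and the original classification rule is not
  stated. The accuracy report surfaces its own rule rather than forcing
  agreement.

## Numerical and testing notes

* The Yates correction is capped at |O − E| (the statistic is exactly 0
  when |O − E| ≤ 0.5), matching the standard R behaviour;
  `scipy.stats.chi2_contingency(correction=True)` implements this cap and
  is used directly, with an independently coded textbook formula as the
  test oracle.
* Holm adjustment is implemented directly (ten lines) because it sits in
  the screen's inner loop; statsmodels' `multipletests` is the oracle in
  tests.
* Kaplan–Meier and log-rank delegate to lifelines; the logistic fit
  delegates to statsmodels GLM, with the sequential deviance table built
  here by nested refits (statsmodels has no Type-I ANOVA for GLMs).
* Problem sizes used by the test suite and the reproduction script:
  parameter recovery uses 10,000-patient cohorts (per-stratum KM medians
  averaged over 6 independent cohorts, since a censored ~1,400-patient
  cell carries ±0.65 months of estimator noise); screen behaviour uses
  200 replicates of 120-patient cohorts; the log-rank null calibration
  uses 1,000 replicates of 200-per-arm samples.

## Known limitations

* At the emulated effect sizes (DC 0.50 vs ~0.19) and cohort size
  (n = 110 evaluable), the proliferation category tops the 41-category
  screen in roughly 80–88% of replicates, and a flat-null screen is
  completely quiet in roughly 80–87% — the screen's single-cohort
  conclusion is reproducible but not near-certain, which is exactly why
  a held-out test set and the combined analysis matter.
* The joint distribution of PD-L1 and proliferation beyond the
  moderately-stratum enrichment is unspecified by the observed marginals;
  the logit shift is exposed as a free parameter rather than a claim.
* The generator's 90-day-shifted exponential is the minimal survival
  model carrying the printed medians; real survival curves need not be
  exponential in either segment.
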