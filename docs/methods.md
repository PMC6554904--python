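# Methods

`readmorbid` implements comorbidity risk-adjustment scoring for Read-coded
primary-care records — the Charlson Comorbidity Index (CCI) and the
Elixhauser Method (EM) — together with a synthetic cohort simulator and a
validation suite for the mortality models those scores feed. This note
records the models, the parameter choices, and the design decisions taken
where the design was genuinely open.

## Code lists and categories

A code list maps terminology codes to the 17 CCI or 31 EM categories.
Codes are opaque, case-sensitive tokens matched exactly after whitespace
trimming; no prefix or hierarchy expansion is performed, because usable
lists are already exploded to individual codes. Duplicates are defined as
identical (code, category) pairs and collapsed on load; the same code
appearing under two *different* categories of one measure is legitimate
(e.g. a tumour code serving both a lymphoma and a metastatic category) and
is surfaced in the validation report rather than deleted. Merging
independently compiled lists is a set union of (code, category) pairs; the
discrepancy report lists codes present in a strict subset of the inputs —
the items human screeners would adjudicate.

Charlson weights ship in the category registry (`data/categories.yml`):
the original scheme (values 1, 2, 3, 6; peripheral vascular disease 1,
metastatic solid tumour 6) and the Quan 12-item update, in which five
categories (myocardial infarction, peripheral vascular disease,
cerebrovascular disease, peptic ulcer, uncomplicated diabetes) receive
weight 0 and the rest weights in {1, 2, 4, 6}. Both tables are transcribed
from the primary weighting literature and are editable, as is the registry
itself. No age points are added to the index: age enters the validation
models as its own continuous covariable.

The packaged lists are **synthetic**: deterministic Read-shaped tokens
(disjoint alphabets per measure, mixed case to exercise case-sensitive
matching) allocated near-evenly across categories, 5832 Charlson and 7156
Elixhauser rows — the scale of the published Read-code resources for these
measures, which cannot be redistributed here. `load_codelist` works
unchanged on real lists in the same CSV schema
(`code,term,category[,weight_original,weight_quan]`).

## Severity hierarchies

Whether a severity hierarchy should be applied before computing the index
is an open design point; the engine applies a configurable rule set,
defaulting to: complicated diabetes supersedes uncomplicated;
moderate/severe liver disease supersedes mild; metastatic solid tumour
supersedes any-malignancy (Charlson); complicated hypertension supersedes
uncomplicated, metastatic cancer supersedes solid tumour, complicated
diabetes supersedes uncomplicated (Elixhauser). Emptying the rule list in
the registry reproduces a no-hierarchy reading. Raw (pre-hierarchy) flags
are always reported alongside the hierarchy-resolved indices so latent-flag
recovery can be checked exactly.

## Look-back windows

Windows are half-open: an event counts iff
`index_date − W ≤ event_date < index_date` (W = 365 d, 5×365 d, or
unbounded). Events on the index date are excluded — the fracture admission
itself should not contribute comorbidities. One event suffices to flag a
category; unknown codes are ignored, as real records are dominated by
non-comorbidity codes. Nesting of the windows makes flags, CCI and EM
counts monotone non-decreasing in window length, which the tests assert
per patient and per category.

## Synthetic cohort generator

The generator emulates the *structure* of a UK primary-care case-control
extract, not any real patient population:

* **Cases** — hip-fracture index dates uniform over 1999-01-01..2013-10-09;
  registration begins at least 3 years (plus an exponential extra with mean
  5 years) before index. Sex is Bernoulli with P(female) = 0.751. Age at
  index is drawn by inverse transform through a piecewise-linear quantile
  function pinned at (q25, q50, q75) = (75, 82, 87) years — the target
  distribution is more left-skewed than common parametric families allow
  (a skew-normal cannot reach this quartile asymmetry), and the quantile
  anchors make the median and IQR match by construction. Ages are rounded
  to whole years and clipped to 40–105.
* **Controls** — synthesized rather than sampled, so matching is exact:
  each case receives `control_ratio` (default 2) controls with identical
  sex, age at index and index date. The matched case's index date is the
  controls' reference date for look-back and mortality outcomes (the
  standard matched-design convention). Control comorbidity prevalences are
  the case prevalences scaled by 0.7.
* **Comorbidity events** — per patient and category a latent flag is
  Bernoulli(prevalence); each present flag emits 1 + Poisson(1) coded
  events with codes sampled uniformly from the category's list and dates
  uniform over [registration start, index). An optional
  `recent_event_fraction` concentrates dates in the final pre-index year to
  stress look-back sensitivity. Latent flags are drawn **independently per
  measure**: the Charlson and Elixhauser flag matrices are uncorrelated
  even for the nine disease areas the two measures share. This keeps
  ground-truth recovery clean but is unrealistic — in real records shared
  categories are nearly identical across measures — so cross-measure
  comparisons on synthetic data quantify each measure's own signal, not
  their real-world overlap.
* **Prevalence defaults** — the relative category sizes are a plausibility
  judgement for an elderly hip-fracture population; the overall level is
  solved exactly (under independence, Σ log(1−p) = log target) so that
  P(zero Charlson categories) = 0.276 and P(zero Elixhauser categories)
  = 0.092 for cases, the burden marginals of the cohort the simulator is
  meant to resemble. Per-category values are configuration, not fact.
* **Mortality** — two-stage logistic model. Death within 30 days of index
  (inclusive) is Bernoulli(expit(β₀ + β_age·age + β_sex·sex + Σ β_c·flag));
  survivors draw death in (30, 365] from the analogous conditional model.
  Defaults (β_age = 0.05/yr, β_sex = −0.30 for female, intercepts −6.9 and
  −5.6, moderate coefficients on cardiovascular, renal, cancer, frailty
  categories) put 30-/365-day case mortality near 8%/29%. Death dates are
  uniform over the realized window; registration end is clipped to them.
  The simulator deliberately uses the same model family the validation
  fits, making coefficient recovery a clean end-to-end check — it cannot
  reveal robustness to misspecification.

One root seed drives a `SeedSequence` spawn per stage (cases, controls,
events, mortality), so identical seeds give bit-identical cohorts and
adding a stage never perturbs earlier stages' draws.

## Validation models

Logistic regressions are fitted by Newton–Raphson maximum likelihood
(statsmodels backend; tolerance 1e-8, ≤100 iterations, deterministic) on
fixed covariable menus — base (age continuous + sex), base+CCI (single
integer score, original or Quan weights), base+EM (31 separate
indicators), each alone, and the 17 Charlson categories as individual
indicators — with no stepwise selection. Constant columns, exactly
collinear columns (pivoted QR) and binary indicators that perfectly
predict the outcome (the sparse-cell separation case) are dropped with a
logged warning, observations never are. Outcome boundaries are inclusive:
death on day 30 is a 30-day death. Cases and controls are analysed
separately; no conditional (matched-pairs) analysis is performed.

AUROC is the Mann–Whitney estimator with ties counted ½, computed via
midranks; its variance and the k-curve equality test use the DeLong
structural-components estimator. For k curves the AUC covariance is
estimated from the paired components, and equality is tested with a
chi-square contrast on k−1 degrees of freedom (for k = 2 exactly the
squared paired z statistic). Confidence intervals are the normal
approximation auc ± 1.96·√var clipped to [0, 1]. A stratified
paired-bootstrap comparison (normal-approximation p from the resampled
difference) is provided as a cross-check only.

One calibration subtlety: the type-I error of the equality test is a
property of comparing *given* score vectors. Scoring the same subjects a
model was fitted on folds each in-sample AUC above ½ and makes the
comparison of two noise models spuriously conservative; the null
calibration experiment therefore fits its two noise models on a separate
training draw and scores fresh subjects, where the test's rejection rate
at α = 0.05 is ~0.047 over 2000 replicates (n = 300).

Kaplan–Meier curves use the product-limit estimator (lifelines backend)
with follow-up capped at 365 days and survivors censored there, stratified
by index band.

## Problem sizes and runtime choices

The test and acceptance workloads are sized for a single CPU: demographic
calibration at n = 10,000 cases; flag recovery and burden marginals at
n = 2,000–4,000; coefficient recovery and EM-vs-CCI discrimination at
n = 20,000 cases per seed; DeLong type-I calibration at 2,000 replicates of
n = 300; bootstrap cross-check at 2,000 resamples of n = 200. Binomial
sampling error at these sizes is well inside the asserted bounds (3σ for
calibration checks).

## Known limitations

* Latent-flag independence across measures (above) — no shared-category
  correlation, no practice-level clustering, no coding-intensity drift over
  calendar time.
* The synthetic code lists carry no clinical meaning; real-list concerns
  (spelling variants, multi-axis Read codes, contentious category
  assignments) are out of scope of what passing tests demonstrate.
* The mortality simulator matches the fitted model family; validation
  results on synthetic data do not measure robustness to model
  misspecification or to informative event-date placement.
* The up-to-standard registration rule is emulated as a simple ≥3-year
  window, not as a data-quality algorithm.
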