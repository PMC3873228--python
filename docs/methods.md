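# Methods

## Study design

The pipeline performs a case–control phenome scan where the *exposure* is
membership in a quantitative-trait group rather than a genotype. For TPMT
activity the cut-points are < 8.5 nmol/h/mL RBC (deficient, "low") and
≥ 15.0 (very high); both are configurable (`TraitCuts`). When a patient
has several assays the earliest is used; later assays crossing a cut-point
only flag the patient as unstable — they stay in their first group.

Analysis time starts at thiopurine initiation. The start date is the
earliest of (i) a CPOE prescription date and (ii) the date of a free-text
report or questionnaire containing a drug name (IMUREL, AZATHIOPRINE,
IMURAN, MERCAPTOPURINE, PURINETHOL; matching is case- and
diacritic-insensitive on alphabetic runs). Records dated the same day as
the start are kept, because report-derived dates carry day resolution
only. Patients without a detected start leave the study population and
are counted in the flow table.

## ICD aggregation and case/control/excluded logic

Codes are normalized to a three-character root plus extension; ordering
and range membership use the root only, since both aggregation schemes
operate at or above the three-character level. Two schemes:

* **Blocks** — one phenotype group per ICD-10 block; the sibling
  exclusion range is the enclosing chapter (C15–C26 → C00–D48). Chapter
  spans ship as a versioned fixture (WHO chapter table) and can be
  overridden.
* **Mapped PheWAS codes** — composition of an ICD-10 → ICD-9-CM crosswalk
  with an ICD-9-CM → PheWAS-code definition table; manual overrides win
  over the automatic composition and are logged; codes that are not a
  proper diagnosis sit on an explicit exclusion list. A code composing to
  two groups without an override is an error, so the map stays
  single-valued. Because the sibling rule is only defined by example for
  the native hierarchy, mapped groups carry an explicit exclusion-range
  column (defaulting to the enclosing chapter in ICD-10 space).

A patient is a case for a group with ≥ 1 qualifying code occurrence (the
"≥ 2 occurrences" convention of earlier phenome scans is available via
`min_occurrences_per_patient`). The at-least-5 filter counts case
patients by default; counting raw code occurrences is a config switch
(`min_cases_unit="occurrences"`) because the published phrasing is
ambiguous between the two readings.

## Lab discretization

Thresholds for the 11 monitored tests live in
`data/lab_thresholds.yaml`. Three rules are study facts (neutrophils
< 1.0 G/L, hemoglobin < 9.0 g/100 mL, hyperglycemia = two results above
the high threshold); the remaining numeric limits are conventional adult
reference values, marked as such in the file, and should be replaced by
site-specific ranges in real use. Comparisons are strict
(value < low, value > high). The two hyperglycemia occurrences must have
distinct timestamps but need not fall in distinct encounters. ALT, AST
and GGT have no low direction. For the frequency arm, results are grouped
by encounter id when present, otherwise one calendar day stands in for
one encounter; patients with no result for a test enter neither arm, so
denominators vary test by test.

## Statistics

* `sample_or_woolf` — cross-product OR, log-scale Wald CI; a zero cell
  triggers Haldane–Anscombe +0.5 on all cells (flagged). This equals the
  Wald interval of an unadjusted logistic fit (checked to 1e-6 in tests).
* `fisher_exact` — two-sided p by the point-probability rule (sum of
  hypergeometric point probabilities ≤ the observed one, with a 1+1e-7
  tie guard, the R/scipy convention); OR = conditional MLE solving
  E[a | margins, ψ] = a by Brent root-finding on log ψ; CI by inverting
  one-sided exact tests at 2.5% per tail. The exact CI and the two-sided
  p follow different constructions and are not guaranteed mutually
  consistent near the boundary; this is a property of the convention,
  not a defect. Degenerate margins give p = 1 and a flagged, undefined OR.
* The ICD and global-lab scans report sample OR + Woolf CI + exact p
  (the combination that reproduces the published screening tables); the
  efficacy comparison defaults to the fully exact estimator. Both are
  selectable everywhere.
* `bh_fdr` — Benjamini–Hochberg step-up per scan; the reported threshold
  is the largest p(i) ≤ i·q/m (0 when none), drawn as the dashed
  Manhattan line. Default q = 0.2.
* `student_t` — pooled-variance two-sided t for the frequency arm.
* `logistic_fit` — ML logistic (IRLS via statsmodels), Wald CIs;
  separation and non-convergence are flagged, with |coef| > 15 treated
  as separation.

## Survival

Event time = days from treatment start to the first qualifying result
after the 7-day washout ("first week": events strictly after day 7
count); follow-up is clamped at 360 days or the last record of any kind,
whichever is earlier. A patient whose only qualifying results fall in
the washout stays event-free. At tied times events precede censorings
(standard convention). Curves are product-limit estimates and the
two-group comparison is the log-rank test (chi-square, 1 df), both via
lifelines behind this module's surface.

## Synthetic cohorts

`SimConfig` fixes the world: 554 patients split 52:413:89 by default,
trait values from truncated normal components centred at 5 / 12 / 17
nmol/h/mL RBC (fixture choices straddling the cut-points; only the
cut-points themselves are study facts), Poisson(7)+1 encounters per
patient, diagnosis codes drawn from the packaged 62-block toy hierarchy
with per-group Bernoulli case status (baseline 0.06, shifted on the odds
scale by injected ORs), lab series with configurable excursion rates,
an exponential first-event clock for the survival event (baseline
1/400 per day, scaled by injected hazard ratios), and report mentions
carrying a drug keyword for 95% of patients. `truth_table` re-derives
the injected effects from the config alone.

What a green recovery test establishes: the scan recovers effects that
are *generated under the scan's own independence assumptions* (codes
independent across groups and patients, no confounding, clean treatment
dates). Real EHR streams violate all of these — correlated codes,
informative encounter timing, OCR'd free text — so fixture-level green
says the machinery is right, not that any clinical inference is.

## Numerical and degenerate-input choices

* Conditional-MLE and CI root-finding: Brent on log ψ, xtol 1e-10/1e-12,
  with geometric bracket expansion; a at the support boundary maps to
  OR 0 or ∞ with the matching one-sided CI bound.
* Scans skip groups with a degenerate 2×2 (zero margin) and groups with
  no case range; exclusion counts always satisfy
  a+b+c+d+excluded = n (tested).
* Empty inputs: empty cohort → empty scan and a zero flow table;
  FDR on an empty vector → no flags, threshold 0; a patient with no
  records is censored at day 0 (logged as degenerate).
* Matching samples without replacement across the whole selection;
  strata shortfalls are warnings carried in the output, not errors.

## Known limitations

* The shipped terminology fixtures are toys (62 blocks, 12 mapped
  groups); real scans need the full WHO hierarchy and a real crosswalk,
  loadable through the same TSV interface.
* Therapy-failure adjudication is consumed as data (a per-patient flag);
  only drug-name detection for treatment dating is automated.
* Fisher p-values are discrete and conservative, so null q-q slopes sit
  slightly below 1 on small cohorts.
* The frequency arm compares means of per-patient fractions with a
  t-test; fractions are bounded and heteroscedastic, which the published
  convention (and hence this implementation) ignores.
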