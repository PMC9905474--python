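# Methods

`irskit` implements a complete real-world-evidence pipeline for a
pan-solid-tumor predictor of PD-1/PD-L1 blockade benefit: from raw
medication records and tumor molecular profiles to therapy lines, survival
endpoints, a locked linear risk score, and the statistics used to validate
it. This note records the models, the defaults and their units, and the
places where a genuinely open design choice had to be made.

## Therapy lines from dose records

Treatment histories arrive as per-dose records (patient, agent, agent
class, start/end date). Two deterministic stages produce lines of therapy:

1. *Course merging.* Per patient and agent, records sorted by start date
   are merged while consecutive start dates are at most `merge_gap_days`
   (default **90 days**, inclusive) apart; a merged course spans the
   earliest start to the latest end.
2. *Line assignment.* Courses are scanned in start order (ties: longer
   course first, then agent name — purely for determinism). A course joins
   the open line unless it starts strictly more than `new_line_delay_days`
   (**30 days**) after the line start, or the fraction of its own duration
   covered by the line span is strictly below `overlap_fraction_min`
   (**0.50**), either of which opens a new line.

The overlap fraction's denominator is the *candidate course's* duration,
not the line's: under this reading a short course fully nested inside a
long line always joins it, which is the clinically sensible behaviour. The
line-relative reading is defensible too; the choice is isolated in
`assign_lines` and exercised by a brute-force day-enumeration oracle in the
tests. A shared single day counts as one day of overlap, and a course's
duration has a floor of one day so single-dose courses are well defined.

Classification: >1 distinct agent ⇒ combination; any member of class
PD-1/PD-L1/CTLA4 sets the line's immuno-oncology class (`mixed` if more
than one); a **first** line of only chemotherapy/hormonal agents ending at
least `adjuvant_gap_days` (**180 days**) before the next line start is
adjuvant — retained with its chronological number but skipped by systemic
line numbering.

## Survival endpoints

rwPFS (time to next therapy) runs from line start to the *effective end
date*: the earliest of death (event) and next-line start (event); with
neither, last-record date if treatment is ongoing (censored), else the
latest member-course end (censored). Two operationalizations had to be
fixed: on a date tie, death outranks the next line (the harder event); and
"ongoing" means the latest member-course end lies within one merge window
(90 days) of the last record date — a conservative proxy for an open
prescription at data cutoff. OS runs from line start to death or last
record. Months are **days / 30.4375** throughout (mean Gregorian month; the
choice only matters in the third decimal of a typical duration).

## Biomarker transforms

Expression is consumed as nRPM: per-sample reads-per-million rescaled so
the median housekeeping target matches its reads-per-million in a reference
sample (`normalize_nrpm`; the scale factor is the median over housekeeping
targets of reference/sample RPM, making the transform invariant to total
read depth). Model features are

* `TMB` = log2(max(TMB, 0.5)) — TMB in mutations/megabase; the 0.5 floor
  keeps zero-mutation samples finite and is half the smallest commonly
  reported non-zero burden;
* per gene: log2(nRPM + 1) − log2(median + 1) — the +1 pseudocount keeps
  zero reads finite and is negligible at typical expression levels.

Centering medians are frozen constants in the model spec (here: the
reference medians of the synthetic generator), never re-estimated per
batch — a locked model must score a given sample identically forever.
TMB-High is the categorical call TMB ≥ 10 Muts/Mb.

## The locked score

IRS = 0.273758·TMB + 0.112641·PD-1 + 0.061904·PD-L1 − 0.077011·TOP2A −
0.057991·ADAM12, dichotomized at 0.873569 (High ⇔ score ≥ threshold).
Higher score predicts longer survival on PD-(L)1 therapy, so the score is
the *negative* of a Cox log-hazard linear predictor; `FitResult` exposes
both hazard-scale and score-scale coefficients to keep the sign convention
explicit.

Re-derivation (`fit_lasso_cox`): features are standardized internally;
scikit-survival's coordinate-descent Coxnet fits a 100-point log-spaced
lasso path from the fully-shrinking penalty down to 10⁻³ of it; the penalty
maximizing mean 5-fold cross-validated concordance wins (folds stratified
by event status, seeded; concordance ties broken toward the sparser model);
the non-zero features are refit by unpenalized Cox (lifelines, Efron ties)
and reported on the input-feature scale. `select_threshold` scans the 1–99
score percentiles, fits the unadjusted High-vs-Low hazard ratio at each cut
(sides with <10 subjects skipped), and returns the full HR-vs-High-fraction
curve plus the largest-High-fraction cut meeting a user-supplied HR target
— the published threshold's exact balancing objective is not quantified, so
the target is a parameter, not a constant.

## Validation statistics

Kaplan–Meier curves with Brookmeyer–Crowley (log-log) median CIs; two-sided
log-rank tests; Cox proportional-hazards fits with Efron tie handling and,
for repeated measures (e.g. a prior-therapy and a checkpoint-inhibitor row
per patient), cluster-robust sandwich variance rather than frailty — the
fixed-effect estimate is unchanged and the sandwich requires no
distributional assumption on the cluster effect. Proportional hazards are
checked with the Grambsch–Therneau scaled-Schoenfeld test (rank time
transform by default); the per-covariate statistic reproduces lifelines'
`proportional_hazard_test` to numerical precision (asserted in the tests)
and the global statistic is computed from the same residuals with
degrees of freedom equal to the number of covariates.

RMST at a fixed horizon (24/36 months in the motivating analyses) is the
area under the KM curve with Greenwood variance; the covariate-adjusted
difference regresses leave-one-out jackknife pseudo-values on group plus
covariates with heteroskedasticity-robust OLS — a standard estimator when
only the adjustment covariates, not the estimator, are specified. The
interaction analysis is a likelihood-ratio test between nested Cox models
(df = number of interaction terms). Sample size/power uses the Schoenfeld
formula d = (z₁₋α/₂+z₁₋β)²/(p(1−p)ln²HR), n = d/event-rate; at n = 180,
HR = 0.5, 1:1 allocation, 50% events it gives 0.908, matching the
published "90% power", and agrees with a Monte-Carlo log-rank simulation
within ±0.02.

## Propensity matching

Logistic propensity model (statsmodels), greedy 1:1 nearest-neighbor
matching without replacement on the **logit**-propensity scale with a
caliper of 0.25·SD of the logit scores (the Rosenbaum–Rubin convention;
the raw-probability scale is a flag since the published wording does not
specify). Treated units are processed in descending propensity order with
seed-shuffled ties; unmatched treated units are dropped and listed, never
silently. Balance: two-tailed t-tests for continuous covariates, Fisher's
exact test for binary categorical ones (chi-square fallback for >2 levels),
flagged at p < 0.05.

## Synthetic cohorts

The generator exists because the patient-level study data are held under
data-sharing agreements; it emulates the *structure* the pipeline assumes,
not any individual dataset.

* **Biomarkers**: Gaussian copula with log-normal marginals. Published
  pan-cohort Spearman correlations are targets (0.571 PD-1/PD-L1, 0.211
  TMB/TOP2A, 0.032 TMB/ADAM12, 0.033 PD-1/TOP2A); unpublished pairs are set
  to plausible values inside the published range. Spearman targets are
  converted to copula parameters by ρ_P = 2·sin(πρ_S/6), exact for the
  Gaussian copula.
* **Defaults** are calibrated to the published discovery-cohort anchors:
  TMB log-normal with median 6.5 Muts/Mb and σ(ln) = 1.15 (≈34% TMB-High,
  between the treated-cohort 31% and the score-High fraction), PD-1/PD-L1
  generator medians 1.35× the reference medians (a modestly
  immune-enriched treated population), giving ≈45% score-High — near the
  published 46%. `SimConfig.with_high_fraction(target)` re-solves the TMB
  location under a quadrature-based normal approximation of the score when
  a different prevalence is wanted.
* **Outcomes**: Weibull proportional hazards (shape 1.2, scale 18 months at
  the mean score) with log-hazard −(score − mean score); censoring is a
  staggered administrative horizon U(3, 30) months plus exponential dropout
  at 0.01/month, giving ≈50% events — the event rate the power analysis
  assumes. Ground truth (linear predictor, uncensored event time) rides
  along for oracle tests.
* **Treatment histories**: four scripted archetypes (monotherapy,
  overlapping combination, gapped re-treatment, adjuvant-then-advanced)
  with known line structure in `truth_*` columns.
* **Full cohorts** (`gen_cohort`) tie the pieces together: dosing runs from
  an index date until the generated progression/censoring time; a
  progression event becomes either a next therapy line or death, so the
  derived endpoints reproduce the generating times.

What the generator does **not** emulate: tumor-type-specific biomarker
distributions, assay-level read noise, panel-version effects,
microsatellite status, informative censoring, or correlation between
biomarkers and treatment choice (except where a test injects it). Passing
tests therefore demonstrate correctness of the *algorithms* under the
stated data-generating assumptions, not clinical performance on real
cohorts.

## Problem sizes and numerical choices

Test and report sizes were chosen so the whole battery runs in minutes on
one core while keeping Monte-Carlo error well inside the asserted
tolerances: rank-correlation checks at n = 20 000 (±0.02), feature
selection over 20 seeded cohorts of n = 2 000, coefficient recovery at
n = 5 000 (within 3 SE), type-I-error calibration at 1 000 replicates
(±2%), power cross-check at 2 000 replicates. Degenerate inputs fail loud:
all-zero housekeeping counts, constant candidate features (dropped with a
warning), all-censored cohorts (reported with a notice instead of fits),
all-equal scores in threshold search, empty matching arms.
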