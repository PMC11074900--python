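# Methods

## Setting and data model

The package models a closed-campus study in which every meal at one of
three cafeterias is paid from a student account, producing a transaction
log (student, date, time, amount, cafeteria, item), and in which each
student completes four screening instruments once: PHQ-9 (depression,
0–27), GAD-7 (anxiety, 0–21), PSS-14 (perceived stress, 0–56) and ISI
(insomnia, 0–28). The default observation window is October 1–31, 2020,
with weekday/weekend taken from the real day of week (an override list can
re-label individual dates, e.g. public holidays; the default applies none).

Screening partitions students into four labels: mild depression
(5 ≤ PHQ-9 ≤ 9), moderate-severe depression (PHQ-9 ≥ 10), healthy controls
(PHQ-9 < 5 and GAD-7 < 5 and PSS-14 < 29 and ISI < 8), and excluded
(sub-threshold depression with comorbid anxiety/stress/insomnia). The
summary-table comorbidity flags use the strict cut-offs GAD-7 > 5,
PSS-14 > 28 and ISI > 8. These disagree with the inclusion cut-offs at the
boundary; both conventions are deliberately kept as two distinct rules
rather than harmonised, because both are in common use and the choice at
the boundary is a reporting convention, not a modelling question.

## Meal segmentation

Within one student-day, transactions are sorted by (time, amount, item)
and grouped greedily: the first transaction anchors a meal, and each later
transaction joins the current meal iff it falls within 7200 s of the
*anchor* (not of the latest member). An anchored rather than sliding
window keeps segmentation order-deterministic and matches the reading that
a meal's window runs from its first record. Meal time = anchor time;
expenditure = sum of member amounts; cafeteria = the anchor's cafeteria.

Meals are classed by the operating slots breakfast 06:30–08:30, lunch
11:00–13:00, dinner 17:30–19:30, bounds inclusive. A meal outside every
slot is assigned to the nearest slot by gap to the interval, ties broken
toward the earlier slot, and flagged `out_of_slot`; a switch discards such
meals instead. If a day yields more than three meals, the three whose
anchors are closest to any slot are kept; if two meals share a class, the
in-slot one wins, then the earlier. All drops are counted and surfaced.

## Feature families

Per student and day-type (weekday/weekend):

* **time** — mean, median, MAD, max, min of meal start times per class
  (seconds since midnight);
* **interval** — the same statistics of within-day start-time gaps for
  breakfast–lunch, lunch–dinner, breakfast–dinner (seconds);
* **expenditure** — the same statistics of per-meal spending (yuan);
* **location** — share of meals at each cafeteria, overall and per class;
* **diversity** — mean number of distinct item codes per observed day;
* **frequency** — fraction of *calendar* days of the day-type with each
  meal class (skipping is the signal, so unobserved days count against);
* **pattern** — frequency of each of the 7 all-day patterns (the set of
  classes eaten that day) over days with at least one recorded meal. A
  day with no transactions is unobservable (the student may be off
  campus), so it enters no pattern denominator; a switch changes the
  denominator to calendar days.

MAD is `median(|x − median(x)|)`, unscaled: no 1.4826 normal-consistency
factor, because the statistic is reported directly in minutes/seconds as a
regularity index, not as a robust SD estimate. A `mad_kind="mean"` toggle
computes the mean absolute deviation instead, since the acronym is
ambiguous in parts of the literature.

Features are z-scored over the full included cohort (all three groups
pooled) with the sample SD (ddof=1, the convention of the major commercial
statistics packages; ddof=0 available). SD bands code each feature as
Rare (z < −1), Normal (−1 ≤ z ≤ 1) or Always (z > 1). An empty cell is
missing, never zero; zero-variance features are dropped with a log entry.

## Statistical models

**ANCOVA.** `feature ~ group + age + gender + bmi_class + education`, the
factors dummy-coded (references: female, BMI 18.5–24, undergraduate). The
group effect is a Type II partial F-test; post hoc contrasts are pairwise
differences of covariate-adjusted group means with Benjamini–Hochberg
adjustment across the three pairs. Across features, FDR is applied within
each feature family by default (the family is the natural hypothesis
batch; scope is configurable). Rank-deficient model matrices raise an
error naming the aliased columns.

**Logistic odds ratios.** For each banded pattern feature, two binary
maximum-likelihood models (mild vs HC; moderate-severe vs HC) with Rare as
the reference band and the covariates above; OR = exp(β) with 95% Wald
CIs. Two binary fits rather than one multinomial model reflect how
per-level ORs against controls are conventionally reported; a multinomial
toggle exists. Quasi-separated fits (non-convergence, |β| > 15 or
SE > 50) are returned flagged `unstable` rather than silently reported.

**Mediation.** Single-mediator path model: M ~ X + covariates gives path
a; Y ~ X + M + covariates gives b and the direct effect c′; the indirect
effect is a·b with a percentile bootstrap CI (default 5000 resamples,
explicit seed, warning below 1000). Default orientation: X = group score
(0/1/2), M = raw GAD-7 total, Y = BLD pattern frequency — the direction in
which the substantive claim (anxiety transmits part of the group
difference in regular eating) is stated; the reverse orientation is one
argument away. The Y-equation is linear and its R² is reported.

**Detection.** RBF-SVM, C = 0.1 and gamma = 0.001 by default, stratified
5-fold cross-validation (4:1 split), macro-averaged precision/recall/F1
and one-vs-rest AUC from decision scores (no probability calibration
step). Grid search maximises mean CV accuracy on folds seeded
independently of the evaluation folds, ties toward smaller C then smaller
gamma. No class reweighting by default (inverse-frequency weights behind
a flag): the cohort imbalance (2222/916/172) is part of the design.

## The synthetic generator

Because the original records are not deposited, the generator emulates the
study conditions with explicit, recoverable parameters. Per (student,
day, meal class): skip with probability `p_skip[class, day-type]`;
otherwise draw the meal time from a normal truncated to the class slot
(slot bounds are given, a timing law is not, and truncation keeps slot
classification unambiguous); expenditure log-normal (positive,
right-skewed); distinct items 1 + Poisson(items_rate − 1) from a 50-item
per-cafeteria catalogue; 1/2/3 transactions with probabilities
0.7/0.2/0.1, amounts split by a uniform Dirichlet (non-anchor amounts
floored to the cent, the anchor takes the exact remainder, so sums are
conserved and non-negative). Extra transaction times are uniform between
the anchor and the slot end, so every transaction lies in exactly one
slot. Surveys are discretised truncated normals inside each group's
screening band; GAD-7 is coupled to the latent PHQ-9 with correlation 0.6
and HC draws are truncated below the HC caps, so screening closure holds
by construction.

Default presets encode the canonical group contrasts. Timing jitter SDs
were set from reported regularity values via MAD ≈ 0.6745σ for a normal
(lunch 1520/1568/1687 s and dinner 2085/2104/2329 s for HC/mild/
moderate-severe); breakfast skip probability rises from 0.25 (HC weekday)
to 0.45 (moderate-severe); dinner expenditure log-mean shifts from
log 10 to log 11.5 yuan; items_rate falls from 3.2 to 2.6; survey
locations/scales follow the groups' published summary statistics.
Cafeteria preferences are identical across groups (no location effect).

What the generator does *not* emulate: within-group heterogeneity of skip
probabilities and appetite (every moderate-severe student shares one
p_skip), anxiety→behaviour paths within group, holidays, menu pricing,
off-campus meals, and item-level nutrition. Three consequences worth
knowing. First, group contrasts are cleaner than real data, so the
detection metrics on synthetic cohorts (binary accuracy ≈ 0.93) exceed
what the real study could achieve; the meaningful check is qualitative —
binary detection beats three-class detection. Second, the Always band of
the BLD pattern contains essentially no moderate-severe students, so that
particular banded OR is quasi-separated and flagged. Third, the
cohort-level mediation indirect effect is honestly near zero — the
generator has no within-group anxiety→behaviour path — so the mediation
machinery is validated by parameter-recovery simulation (known a, b)
rather than by the simulated cohort.

## Numerical and testing choices

* Determinism: one `numpy` Generator drives a whole simulation; the
  pipeline's global seed fans out to per-stage seeds through a fixed
  `SeedSequence` derivation; identical configs reproduce artifacts byte
  for byte.
* Sorting is stable on (time, amount, item) so tied timestamps cannot
  reorder segmentation.
* Calibration suites: ANCOVA type-I error at 500 null replicates
  (n = 50/group), logistic CI coverage at 400 replicates (n = 250),
  mediation CI coverage and null rejection at 150 replicates
  (n = 300, 1000 resamples each). Parameter recovery runs 100 replicates
  at 200 students/group over 31 days.
* The timing-jitter recovery check uses a dedicated configuration with the
  moderate-severe lunch jitter doubled relative to HC. Under the
  default presets the MAD contrast is deliberately subtle (≈ 1 standard
  error of the group-mean difference at 200/group — the original contrast
  was detected at 2222 vs 172), so a ≥95% ordering requirement is a
  property of the doubled-jitter configuration, not of the defaults;
  breakfast frequency, dinner expenditure, diversity and pattern
  orderings are strong under the defaults and are tested there.
* Truncation to the slot shrinks the realised timing MAD relative to
  0.6745σ (by ~5% at σ = 1520 s), and the per-student sample MAD over
  ~20 meals is biased slightly low; reported synthetic MADs therefore sit
  a little under the nominal preset values.

## Known limitations

Meal identity is inferred purely from payment timing; shared payments,
off-campus or skipped-but-eaten meals are invisible. The item catalogue
is synthetic, so diversity is a count of codes, not foods. Printed
odds ratios and detection metrics from the original cohort are not
reproducible from synthetic data and are not targets of this package.
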