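# mealprint

Digital dietary phenotyping for depression screening research. On a closed
campus where every cafeteria meal is paid electronically, the payment log is
a passive, month-long record of *when*, *where*, *how much* and *how
variedly* a student eats. `mealprint` turns such transaction logs plus a
one-shot screening survey (PHQ-9, GAD-7, PSS-14, ISI) into per-student
dietary behaviour features, covariate-adjusted group statistics and an
SVM-based depression detector — and ships a synthetic-data generator with
known ground truth, because real student records of this kind are not
publicly deposited.

It is intended for researchers in behavioural epidemiology and digital
mental health who want a tested, reproducible reference implementation of
this analysis pipeline.

## The analysis

1. **Screening** — groups from survey totals: mild depression
   (5 ≤ PHQ-9 ≤ 9), moderate-severe (PHQ-9 ≥ 10), healthy controls
   (PHQ-9 < 5, GAD-7 < 5, PSS-14 < 29, ISI < 8); remaining students
   (comorbid symptoms without depression) are excluded.
2. **Meal segmentation** — within a student-day, the first transaction
   anchors a meal and every transaction within 2 h of the anchor joins it;
   meals are classed by the cafeteria operating slots breakfast 06:30–08:30,
   lunch 11:00–13:00, dinner 17:30–19:30 (out-of-slot meals are assigned to
   the nearest slot and flagged), at most one meal per class per day.
3. **Features** — per student, split by weekday/weekend: summary statistics
   (mean, median, MAD, max, min) of meal times, inter-meal intervals and
   per-meal expenditure; cafeteria visit shares; mean distinct food items
   per day; per-class meal frequency; and the frequency of the 7 all-day
   patterns (B, L, D, BL, LD, BD, BLD).  MAD is the unscaled median
   absolute deviation, `median(|x − median(x)|)`, used as an
   eating-regularity index.
4. **Statistics** — ANCOVA (feature ~ group + age + gender + BMI +
   education) with Type II partial F-tests, pairwise adjusted-mean
   contrasts under Benjamini–Hochberg FDR; logistic odds ratios of
   SD-banded pattern frequencies (Rare z < −1 / Normal / Always z > 1,
   Rare as reference) for each depression level vs controls; and
   single-mediator analysis (group → anxiety → pattern frequency) with a
   5000-resample percentile bootstrap CI on the indirect effect a·b.
5. **Detection** — RBF-SVM (C = 0.1, gamma = 0.001, chosen by grid search)
   on z-scored features with stratified 5-fold cross-validation (4:1
   train:validation), reporting accuracy, macro precision/recall/F1 and
   one-vs-rest macro AUC.

## Worked example

```python
import mealprint as mp

cfg = mp.default_config({"HC": 200, "mild": 100, "moderate_severe": 60}, seed=11)
survey, log, truth = mp.generate_cohort(cfg)
meals = mp.MealSegmenter().fit_transform(log)
feats = mp.DietaryFeatureExtractor(cfg.calendar).fit_transform(meals)
groups = survey.set_index("student_id")["group"]
print(feats.groupby(groups)[["time.weekday.lunch.mad",
                             "frequency.weekday.breakfast",
                             "pattern.weekday.BLD"]].mean().round(3))
```

```
                 time.weekday.lunch.mad  frequency.weekday.breakfast  pattern.weekday.BLD
group
HC                              980.430                        0.753                0.610
mild                            984.920                        0.720                0.585
moderate_severe                 985.225                        0.540                0.426
```

Read: controls eat breakfast on 75% of weekdays versus 54% in
moderate-severe depression, and take all three meals on 61% of observed
weekdays versus 43% — the moderate-severe group skips breakfast more and
drifts toward a lunch-dinner-only day.  Lunchtime regularity (~16 min MAD)
barely separates groups at this small sample; the preset timing contrast is
subtle, and ordering it reliably needs larger cohorts (see
`docs/methods.md`).

The same run end-to-end, from the shell:

```bash
mealprint run-all --n-per-group 200,100,60 --seed 11 --out runs/demo
```

writes `survey.csv`, `transactions.csv`, `meals.csv`, `features.csv`,
cohort summary, ANCOVA/logistic/mediation reports, SVM metrics and a
manifest (config hash, per-stage seeds and row counts) under `runs/demo/`.

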