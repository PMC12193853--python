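# hypowatch

Personalized, noninvasive hypoglycemia detection from consumer-smartwatch
streams, for researchers in digital diabetes care who want a tested,
reproducible reference pipeline — from raw multi-rate sensor exports to
per-participant model reports and feature-importance tables.

## The problem and the method

People with type 1 diabetes experience hypoglycemic episodes (interstitial
glucose < 4 mmol/L sustained for ≥ 15 minutes) that invasive monitoring does
not always prevent. Hypoglycemia elicits measurable physiological responses —
tachycardia, reduced heart-rate variability (HRV), hyperventilation — that a
wrist-worn wearable can observe. `hypowatch` implements a personalized
detection analysis on top of such data:

1. **Timeline assembly.** Each channel (glucose every 5 min, heart rate /
   steps / energy every minute, HRV every 15–30 min, respiratory rate every
   15 min and blood oxygen every 30 min during sleep) is merged onto a
   1-minute grid. Imputation is bounded and leakage-safe: glucose is
   backfilled ≤ 5 min; HRV/RR ≤ 15 min and blood oxygen ≤ 30 min are
   forward-filled; heart rate, steps and energy are never imputed.
2. **Outcome labeling.** Minute *t* gets label 1 iff it lies in a maximal run
   of minutes with glucose < 4 mmol/L of length ≥ 15; nocturnal events longer
   than 180 min are truncated there.
3. **Day/night segmentation.** Diary sleep times cut the record into uniquely
   identified wake→sleep ("day") and sleep→wake ("night") segments, modeled
   separately with 13 and 10 input features respectively (cardiac, activity,
   respiratory, cyclic time-of-day sin/cos, and manual meal/insulin features,
   including a stepwise 100/75/50/25 % insulin-on-board decay over 4 h).
4. **Leave-hypo-segment-out modeling.** For each (participant, kind), every
   event-bearing segment is held out once as the test set; the remaining
   segments train an XGBoost classifier (L1 = L2 = 10) on a 1:1 randomly
   undersampled training set, repeated over 10 undersampling seeds. The test
   segment keeps its natural imbalance. AUROC summarizes discrimination; the
   operating point maximizes Youden's J = sensitivity + specificity − 1, and
   event detection (any minute / first 15 minutes) is reported at that point.
5. **Interpretability.** Exact TreeSHAP attributions on held-out rows are
   averaged (mean |φ|), normalized to percentages per model, and rolled up
   into cardiac / activity / respiratory / manual / time categories.

A fully seeded synthetic cohort generator emulates the sensor cadences,
missingness and diary structure of a free-living smartwatch + CGM study, with
configurable hypoglycemic event rates and physiological effect sizes, so the
whole pipeline is testable end-to-end without any real participant data.

## Worked example

```python
from hypowatch import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(simulate=CohortConfig(n_participants=4, days_per_participant=10), seed=0)
result = run_pipeline(cfg)
print(result.cohort.summary())
```

```
Cohort Summary (personalized models)
========================================================
Models:                 8
AUROC:                  0.899 +/- 0.078
Sensitivity:            0.895
Specificity:            0.887
Events detected (any):  100.0% of 30
Events detected (<=15min): 99.7%
--------------------------------------------------------
Day feature-category importance (%):
  cardiac         73.7
  time            12.4
  activity        11.0
  manual           2.9
--------------------------------------------------------
Night feature-category importance (%):
  cardiac         79.3
  respiratory     10.5
  time             9.1
  manual           1.1
========================================================
```

Eight personalized models were built (one day and one night model for each
of four synthetic participants). The cohort mean AUROC of 0.90 reflects the
default injected effect sizes (+10 bpm heart rate, −15 ms HRV during
events); with all effects set to zero the same pipeline hovers around 0.5,
confirming that discrimination comes from the injected physiology and not
from leakage. Category importances show the cardiac channels — the ones
carrying the largest injected responses — dominating both models.

Per-model results follow the statsmodels pattern:

```python
res = result.results[0]          # a PersonalizedResults object
print(res.summary())             # AUROC ± SD, Youden operating point, detections
res.feature_importance()         # per-feature Shapley shares (%)
```

The same pipeline runs from the shell:

```bash
hypowatch simulate --config cohort.yaml --out data/ --seed 7
hypowatch run --config run.yaml --out reports/ --seed 7
```

`reports/` then contains per-model JSON/CSV reports, cohort summaries,
importance tables and a manifest recording every constant and library
version used.

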