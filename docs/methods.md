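# Methods

This note documents the models, rules and numerical choices implemented in
`hypowatch`, the assumptions behind them, and what the synthetic cohort can
and cannot demonstrate.

## Outcome definition and labeling

A minute is hypoglycemic when it belongs to a maximal run of consecutive
minutes with interstitial glucose strictly below 4.0 mmol/L lasting at least
15 minutes. Choices within that rule:

* **Strict threshold.** Glucose exactly 4.0 mmol/L is not low; a single
  such minute breaks a run.
* **Missing glucose breaks a run.** When a gap exceeds the 5-minute backfill
  limit, the run ends. This is conservative: events are never fabricated
  across CGM dropouts, at the cost of occasionally splitting one
  physiological episode into two labeled events.
* **Minute grid, not raw samples.** The ≥ 15-minute criterion is evaluated
  on the backfilled 1-minute grid. Because backfill pulls each 5-minute CGM
  sample up to 4 minutes earlier, a labeled run's boundaries sit within one
  CGM sample of the underlying excursion; borderline 15–19-minute dips can
  differ from a raw-sample reading of the same rule.
* **Nocturnal truncation at 180 minutes.** Night events longer than 180 min
  keep their first 180 labeled minutes and are flagged `truncated`; the rule
  is read as label truncation, not event discard, and applies to night
  segments only (assignment by event onset). Very long label blocks teach an
  onset detector little and dominate the positive class otherwise.

## Timeline assembly and imputation

All channels are floored to their containing minute; multiple readings
within one minute are averaged (cadence-robust and order-independent; a
keep-first rule would depend on sub-minute device timing). Imputation is
bounded by each channel's measurement cadence and never crosses it:

| channel | rule | limit |
|---|---|---|
| glucose | backfill from next observation | 5 min |
| HRV, respiratory rate | forward fill | 15 min |
| blood oxygen | forward fill | 30 min |
| heart rate, steps, energy | none | — |

Limits are inclusive: a cell exactly `limit` minutes from its source is
filled. Fills always derive from *observed* cells, never from previously
imputed ones, which makes both imputations idempotent and keeps every
imputed cell within its limit of a real measurement (this is asserted by
flag-distance audits in the tests). Glucose backfill is the only
backward-in-time fill; it only feeds the outcome label, not the predictors,
so the predictor path never sees future information. Unimputed channels are
left missing — the tree ensemble learns default split directions for missing
values natively.

## Diurnal segmentation

Diary sleep times are authoritative. Days span wake→sleep onset, nights
sleep onset→next wake; identifiers encode participant, date and kind. The
partial stretches before the first wake and after the last wake are dropped.
Night modeling is additionally gated by a sleep-consistency heuristic:
the circular SD of sleep-onset hour must not exceed 3 h and no night may be
shorter than 3 h. (Circular statistics stop a 23:30/00:30 alternation from
counting as a 23-hour spread.) The gate is a stand-in for a narrative
exclusion of shift-work-like schedules; both constants are configurable.

## Features

Fifteen variables in total; 13 in the waking schema, 10 in the sleeping
schema. All windows are trailing (causality requires it; "rolling" is
otherwise orientation-free):

* heart rate: 10/30/60-min trailing means over non-missing minutes;
* HRV: last (bounded-fill) value, plus the difference between the two most
  recent raw observations, held until the next observation and missing
  before a second observation exists;
* steps and active energy: 30/60-min trailing sums, missing minutes count 0;
* blood oxygen and respiratory rate (sleeping schema only): last value;
* time of day: sin/cos of the fractional hour (fractional rather than
  integer hour for smoothness across the night; configurable upstream of the
  encoding if integer hours are wanted);
* time since last meal (waking schema only): whole hours (floor) since the
  most recent diary meal, capped at 12 h, missing before the first meal;
* insulin on board: stepwise 1.0 / 0.75 / 0.5 / 0.25 over the four hours
  after the most recent short-acting dose (half-open hour bins, the dose
  minute belongs to hour 1), 0 afterwards. Doses are unit-less diary ticks,
  so overlapping doses do not stack — the most recent dose resets the clock.

One schema ambiguity deserves a note: enumerating the sleeping variables
(3 HR + 2 HRV + blood oxygen + respiratory rate + 2 time + meal + insulin)
gives 11, while the analysis design fixes the sleeping schema at 10
features. We resolve this by omitting time-since-meal at night: overnight it
saturates at its cap within hours and is nearly constant, so it is the
member whose removal costs the least information. Participants without meal
records are modeled without the meal feature (12 waking features; the
sleeping schema is unaffected).

## Personalized modeling

Each (participant, kind) dataset is split by the leave-hypo-segment-out
scheme: one iteration per event-bearing segment, holding that segment out as
the test set and training on all other segments of the same kind. Iterations
are trained independently; nothing flows between them. A kind with a single
event-bearing segment is effectively unmodelable (its only iteration has no
training positives) and is dropped with a warning.

Training sets are balanced 1:1 by randomly undersampling non-hypo minutes
(positives untouched, temporal order preserved, no upsampling when negatives
are already the minority); the ratio is configurable. Test sets are never
resampled. The whole procedure repeats over 10 undersampling random states.

Features are z-scored with statistics estimated on the training rows only
(the safe reading of "standardize before training"; a `global` scope flag
reproduces pooled scaling). Zero-variance features are centered, not
divided; missing cells stay missing.

The classifier is XGBoost's gradient-boosted trees with `reg_alpha = 10` and
`reg_lambda = 10`; every other hyperparameter stays at the library default
(e.g. 100 boosting rounds, `max_depth` 6 in xgboost ≥ 2) and is recorded in
the run manifest. Fits are single-threaded and seeded, so reruns reproduce
scores exactly.

Evaluation per iteration: AUROC over all test minutes; the Youden operating
point is found by exhaustive search over distinct score cut-points using
integer confusion counts (exact tie handling; ties break toward the higher
threshold), computed on the test scores to mirror per-iteration reporting —
this is optimistic, and a `threshold_source="train"` option derives the
threshold from training scores instead. Event detection at that threshold is
recorded per event: any positive minute during the event, and any within its
first 15 minutes. Iterations whose test segment contains a single class are
flagged invalid and excluded from averages.

Aggregation: metrics are averaged over seeds within each iteration, then
over iterations (each hypoglycemic day/night weighs equally); the cohort
summary is the mean ± SD over personalized models, with event detection
rates pooled over all (event, seed) evaluations.

## Interpretability

Per-row attributions are exact TreeSHAP values computed by XGBoost itself
(`pred_contribs=True`); local accuracy (base value + Σφ = margin) is asserted
in the tests, alongside a brute-force subset-enumeration Shapley oracle on
tiny ensembles. Attributions are computed on each iteration's held-out rows,
their absolute values averaged over rows, iterations and seeds, normalized
to percentages within a model, and rolled up into categories (cardiac:
HR + HRV; activity: steps + energy; respiratory: blood oxygen + respiratory
rate; manual: meal + insulin; time: sin/cos). Cohort-level importance
averages the per-model *percentages* — not raw magnitudes — so models with
larger margins do not dominate, and a category's share always equals the sum
of its members'.

## Synthetic cohort

The generator emulates the data environment the analysis assumes, not
glucose physiology:

* **Glucose** is a mean-reverting Gaussian walk (baseline 7.0 mmol/L,
  reversion 0.03/min, step SD 0.25 mmol/L) floored at 4.6 mmol/L outside
  events; ground-truth event intervals force it into 3.0–3.9 mmol/L. Short
  (5–10 min) sub-threshold dips are injected at a low rate to exercise the
  duration filter; events keep 15-min margins from segment edges and each
  other so labeling recovers the truth set exactly (within one CGM sample).
* **Cadences** follow the study's measurement table: glucose 5 min; HR,
  steps, energy 1 min; HRV 15 min at night and a Bernoulli-thinned (keep
  0.5) 15-min grid by day, mimicking restful-state-only daytime HRV;
  respiratory rate 15 min and blood oxygen 30 min during sleep only.
* **Physiological responses** are level shifts over event minutes (default
  lag 0, configurable): +10 bpm HR, −15 ms HRV, +2 breaths/min, −2
  percentage points blood oxygen. These defaults are illustrative magnitudes
  in the range the physiology literature associates with sympathoadrenal
  activation; the source analysis reports no effect sizes of its own, so no
  claim of estimation is made.
* **Activity** is a two-state rest/active Markov chain over waking minutes
  (P(rest→active) = 0.08, P(active→rest) = 0.25) driving step bursts
  (~90/min active) and energy; HR couples to steps at 0.08 bpm per
  step/min. Steps and energy are zero during sleep.
* **Diary**: 3 meals/day at breakfast/lunch/dinner anchors with 30-min
  jitter, insulin after each meal with probability 0.8, sleep 23:00–07:00
  with 20-min jitter. Event rates default to 0.5/day segment and 0.3/night.
* **Determinism**: a cohort seed spawns per-participant seeds via
  `SeedSequence`; per-participant child streams separate diary, events,
  glucose and wearables, so outputs are byte-identical per (config, seed).

What passing tests on this cohort do **not** show about real data: the
generator has no sensor drift or artifacts, no meal/insulin–glucose
coupling (events are placed independently of the diary), no inter-individual
response heterogeneity, and level-shift effects are easier to detect than
real, lagged, variable-magnitude responses. Results on it validate the
pipeline's correctness and leakage-safety, not clinical performance.

## Problem sizes in the test suite

The end-to-end checks run a 4-participant × 10-day cohort at the default
effect sizes (and a matched zero-effect cohort) with all 10 undersampling
seeds — about 8 personalized models and ~600 classifier fits per cohort —
and a 3-participant cardiac-effects-only cohort for the importance checks.
These sizes give stable cohort means while keeping the whole suite fast on a
single core.

## Known limitations

* Test-derived Youden thresholds (the default, mirroring per-iteration
  reporting) overstate deployable sensitivity/specificity; use
  `threshold_source="train"` for an honest operating point.
* Sub-minute duplicate handling (mean) and the sleep-consistency heuristic
  are reasonable defaults, not validated conventions.
* The pipeline assumes one fixed clock offset per participant; timezone
  changes mid-study are out of scope.
* Boosting rounds and learning rate are library defaults; no tuning is
  performed beyond the fixed regularization.
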