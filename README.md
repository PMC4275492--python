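# yapcal

Calibration toolkit for **segmented-day youth physical-activity
self-reports** against accelerometer-measured moderate-to-vigorous
physical activity (MVPA).

Self-reported activity scores from school-age youth are cheap to collect
but inaccurate on their own. Calibration converts them into the metric
of an objective criterion: each questionnaire item targets a discrete
daily time window (recess, PE class, lunch, the evening, Saturday, ...),
the matching window is cut out of a minute-level activity-monitor
record, and a per-item regression maps the ordinal score — together with
age and gender — onto the percent of window time spent in MVPA. The
calibrated per-item predictions are then weighted by each window's
scheduled minutes and weekly frequency and summed into school,
out-of-school and weekly minutes of MVPA. The package is aimed at
measurement researchers building or refining such instruments, and ships
a synthetic-cohort simulator so the entire workflow runs, and is tested,
without any participant data.

## The model

For item *k* with matched window *w*, calibration fits by ordinary least
squares

> %MVPA<sub>w</sub> = β₀ + β₁·age + β₂·gender + β₃·score<sub>k</sub> + ε,  ε ~ N(0, σ²)

where %MVPA<sub>w</sub> is the participant's mean percent time in MVPA
over their *valid* occurrences of window *w*, gender is coded 0/1
(female/male) and score<sub>k</sub> ∈ {1..5}. Because some items
relate to monitor data nonlinearly (rising through mid-scale scores,
then plateauing at the top of the scale), the score term can instead be
entered categorically — one level effect per observed score — with an
information criterion (BIC by default) choosing the encoding per item.

Around the regression sit the field's standard data-reduction rules:

- **Segmentation** — ten window types per week, anchored to each
  school's start/end times (commutes ±30 min, before-school 60 min,
  after-school until 18:00, evening 18:00–22:00, weekend days
  07:00–22:00), with recess/PE/lunch times supplied per date.
- **Screening** — a window occurrence is valid when worn + imputed
  minutes cover ≥ 70% of its scheduled minutes; a participant enters an
  item's calibration with ≥ 3 valid occurrences of its window (≥ 1 for
  PE, Saturday and Sunday). Item-wise screening provably retains a
  superset of the traditional whole-week screen, which is the point:
  per-item sample sizes are maximized.
- **Nonwear imputation** — documented nonwear bouts from participant
  activity logs receive the logged activity's compendium MET value,
  counting toward both wear compliance and %MVPA.
- **Evaluation** — individual vs group percent error (group error is
  the mean of signed individual errors, so aggregation dilutes it), and
  group-level equivalence by two one-sided tests (TOST): measures are
  equivalent when both one-sided 95% confidence bounds of the mean
  paired difference fall inside ±10% of the accelerometer group mean.
- **Design** — sample size for the questionnaire's incremental R²
  (default: full R² 0.35 with 3 predictors vs reduced 0.25) from the
  noncentral F distribution with f² = (R²f − R²r)/(1 − R²f).

## Worked example

Run the bundled demo pipeline (simulate a 120-youth cohort, segment,
screen, calibrate, score, evaluate):

```bash
yapcal run --n 120 --seed 7 --out demo_out
```

which prints

```
{"out_dir": "demo_out", "group_error_pct": -0.046, "equivalent": true}
```

`demo_out/models.json` then holds one exportable equation per item,
e.g. for the evening item (linear encoding chosen over categorical by
BIC, 851.4 vs 865.4):

```
%MVPA_evening = 6.61 - 0.066*age + 0.73*gender + 4.34*score   (n=119, R^2=0.28)
```

`demo_out/agreement.json` reports held-in agreement between calibrated
and monitor-based weekly MVPA minutes: individual errors span −51.1% to
+39.1% of the monitor mean (mean absolute error 13.0%) while the group
error is −0.05% — individual prediction is noisy, group estimation is
accurate, which is the central trade-off the method exploits.
`demo_out/equivalence.json` shows the TOST verdict: the 95% one-sided
bounds [−28.5, +27.5] min/week sit well inside the ±109.7 min/week
(±10%) region, so the calibrated instrument and the monitor are
group-equivalent on this cohort.

The same stages are available as separate verbs (`yapcal simulate`,
`segment`, `screen`, `calibrate`, `score`, `equivalence`, `power`) and
as a Python API; the calibration core is a scikit-learn-style estimator
(`ItemCalibrationRegressor`) that composes with sklearn tooling.

```python
import yapcal as y

cohort = y.simulate_cohort(y.simulate.paper_like_config(200, seed=1))
result = y.holdout_cross_validate(cohort, split_fraction=0.3, seed=1)
print(result.agreement.group_error_pct, result.equivalence.equivalent)
```

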