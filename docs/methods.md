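# Methods

This note documents the statistical procedures implemented in `yapcal`,
the assumptions behind them, the simulator used to exercise them, and
the numerical and design choices that were genuinely open.

## 1. Segmented-day linkage

The instrument is a 7-day recall with 15 items in three sections
(activity at school, activity out of school, sedentary). Ten activity
items are each linked to one window type of a weekly processing
schedule; the five sedentary items are scored (section mean of
non-missing items) but never calibrated, since the criterion below is an
MVPA measure.

Window bounds are derived from each school's clock times:

| window | date rule | bounds |
|---|---|---|
| before school | every weekday | 60 min before commute start → commute start |
| commute to school | every weekday | 30 min before school start → school start |
| recess / PE / lunch | school-provided dates | provided start → provided end |
| commute from school | every weekday | school end → school end + 30 min |
| after school | every weekday | commute end → 18:00 |
| evening | every weekday | 18:00 → 22:00 |
| Saturday / Sunday | weekend | 07:00 → 22:00 |

Minute intervals are half-open `[start, end)` with each minute labelled
by its interval start. This is a convention choice (the bound
assignment at window edges is not standardized in the field); it
guarantees the partition property — no minute can enter two windows —
which the test suite asserts against a naive per-minute assignment
oracle on random schedules. Recess, PE and lunch require explicit
per-date times and are simply absent on dates without them; supplying
overlapping windows is a validation error, not a silent re-assignment.

When a stream carries only energy expenditure, the MVPA flag is derived
as EE ≥ 3.0 METs (the conventional moderate-intensity cut; the
threshold is a parameter).

## 2. Screening and imputation

A window occurrence is **valid** when `(worn + imputed) / scheduled ≥
0.70`. Both boundaries are inclusive ("at least" is taken literally)
and the fraction is per window occurrence, not per day — the compliance
requirement attaches to each time window of interest. A participant
enters item *k*'s calibration when window *k* has ≥ 3 valid occurrences
in the week; PE, Saturday and Sunday occur at most a few times per week
and require only ≥ 1. Two modes:

- `item_wise`: retention decided per (participant, window type);
- `whole_week`: a participant is kept for all items only if every
  scheduled window type meets its requirement.

The item-wise retained set for every window type is a superset of the
whole-week set by construction, and retention is monotone in both
thresholds; both properties are asserted as tests.

**Imputation.** Documented nonwear bouts from the daily activity log
assign the logged activity's MET value (from a user-supplied
label → MET lookup; a small default table ships for testing) to nonwear
minutes the bout covers. The first covering log entry wins when entries
overlap; worn minutes are never altered; entries whose label is missing
from the lookup are skipped with a warning and recorded in the audit.
Imputed minutes count toward *both* the 70% validity fraction and
%MVPA: the purpose of imputation is to maximize the usable sample, and
counting it only toward %MVPA would leave the affected windows invalid
anyway. This is a deliberate interpretation; the alternative (validity
from worn minutes only) would make screening strictly harsher.

## 3. Calibration regressions

Per item: OLS of mean %MVPA (over the participant's valid occurrences
of the matched window, each occurrence weighted equally) on age
(continuous years), gender (0 = female, 1 = male) and the item score.
Assumptions are the usual fixed-effects OLS ones: independent,
homoskedastic, normal errors; a Jarque–Bera p-value is stored per model
as a residual-normality summary. The outcome is *percent* of window
time rather than minutes so coefficients are comparable across windows
of different lengths; conversion to minutes happens only at the
composite stage.

**Encoding.** `linear` enters the score with a single slope;
`categorical` enters one level effect per observed score
(treatment-coded against the lowest observed level), which can follow a
rise-then-plateau shape. Under `encoding="auto"` both are fitted and
the lower information criterion wins, ties going to linear. The default
criterion is **BIC** rather than AICc: BIC's selection is consistent, so
a truly linear item keeps the linear encoding with probability → 1 as n
grows, while a clear plateau (whose deviance gain grows linearly in n)
is still detected; AICc keeps a constant ≈ 11% chance of spuriously
preferring the 3-extra-parameter categorical encoding however large the
sample. AICc and AIC remain available via `criterion=`.

Degenerate designs (constant score, rank deficiency, or too few rows
for the floor of 10 observations per coefficient — configurable) raise
an explicit error; under `auto`, a failed categorical fit falls back to
linear with a warning. Prediction at a score level unseen at fit time
(categorical only) uses the nearest observed level.

**Composites.** Per-item predicted %MVPA is clipped to [0, 100]
(predictions are reported untransformed; no logit or similar — a
documented simplification) and converted to minutes as
`pct/100 × minutes-per-occurrence × occurrences-per-week`, both taken
from the materialized weekly schedule (weekday windows × 5, weekend × 1,
recess/PE/lunch × their scheduled weekly count). School and
out-of-school composites sum their five items; weekly = school +
out-of-school. A missing item response contributes the model's
prediction at the cohort-mean score and is flagged (policy `skip`
omits the item instead).

Season is carried through the dataset as an optional covariate but is
off by default; the generating designs balance it rather than model it.
Mixed-effects variants are out of scope: the calibration equations are
fixed-effects OLS.

## 4. Evaluation

**Agreement.** Individual error for participant *i* is
`(pred_i − obs_i) / mean(obs) × 100`; the group error applies the same
formula to the group means and therefore equals the mean of the signed
individual errors, so `|group| ≤ mean |individual|` identically —
aggregation dilutes individual error. Pairs with missing values are
dropped and counted.

**Equivalence (TOST).** Paired differences `pred − obs`; one-sided
(1 − α) bounds `mean ± t_{1−α, n−1}·se`; equivalent iff both bounds lie
strictly inside `± region × mean(obs)` with region 0.10 by default.
Note the "two one-sided 95% CIs" phrasing and the conventional
TOST-via-90%-two-sided-CI are the same procedure — the one-sided 95%
bounds *are* the endpoints of the 90% two-sided interval — so a single
construction serves both descriptions. Zero-variance differences are
handled exactly (the verdict follows from the constant difference).
With the true mean difference exactly on the boundary the probability
of declaring equivalence equals α; the test suite verifies ~5% by
simulation. The paired-difference construction itself is a design
choice: group-summary variants exist, but a paired design is implied by
per-participant differences between two measures on the same cohort.

**Power.** For the incremental R² of the questionnaire score over age
and gender: f² = (R²_full − R²_reduced)/(1 − R²_full), tested with a
noncentral F with df₁ = tested predictors, df₂ = n − k − 1 and
noncentrality λ = n·f² (the convention used by common power software;
Cohen's λ = f²(df₁ + df₂ + 1) differs by a few observations at these
effect sizes). `sample_size_r2_change` returns the smallest n with
power ≥ target and is verified self-consistently at n and n − 1.
Defaults R² 0.35/0.25 with 3 predictors reflect typical
self-report-vs-monitor agreement in youth. "Random factors" power
formulations are deliberately not implemented; only the R² values are
specified, so the fixed-effects R²-change computation is used.

**Hold-out cross-validation** splits participants (deterministic given
seed), fits all item models on the training split, and compares
predicted weekly minutes with monitor-based weekly minutes on held-out
participants. Observed weekly minutes mirror the composite weighting
and require ≥ 1 valid occurrence of every activity window type, so the
two sides cover the same windows.

## 5. The synthetic-cohort simulator

The simulator emulates the four pipeline inputs with the structure the
calibration assumes. Latent model, per participant:

- true %MVPA per window type ~ Normal(μ_w + age-group shift + gender
  shift + season shift, σ_w) truncated to [0, 100]; daily occurrences
  add N(0, day-to-day SD), clipped;
- item score = pseudo-inverse of a monotone item link applied to the
  latent value, plus rounded Gaussian reporting noise, clipped to 1–5
  (on a plateau the score is uninformative and spread uniformly over
  [knot, 5]);
- minute streams realize each window's %MVPA as Bernoulli minutes after
  adding monitor measurement noise; EE values are drawn conditional on
  the MVPA flag;
- nonwear bouts per day ~ Poisson with an age-graded rate,
  gamma-distributed durations, placed uniformly in the waking day; a
  configurable fraction is documented in the log with an activity label
  drawn from the MET lookup.

Key defaults (all overridable): equal elementary/middle/high mix with
ages 8–11/11–14/14–18; balanced genders; window means 10–45 %MVPA
declining with age (−4 elementary→high per group step… +4/0/−4 shifts),
+3 for boys, ±2 by season; between-participant SD 8, day-to-day SD 6,
measurement SD 3 (%MVPA units), reporting SD 0.6 score units; item
links linear at 8 %MVPA per score unit, with a knot-4 plateau on the PE
item; nonwear 1.5/2.5/3.5 bouts/day (elementary/middle/high) of mean 90
min, 60% documented. The distributional parameters for youth %MVPA per
window are not published values — they were chosen once for face
validity so that overall wear lands around 70–85% of the waking day
(falling with age) and screening produces a visible item-wise vs
whole-week retention contrast. A single shared seed is split per
participant, so enlarging a cohort never reshuffles earlier
participants.

Two special modes support exact checks: `noiseless_config` switches all
noise off and realizes window %MVPA deterministically
(`round(p·m)/m`, i.e. quantized to the minute grid), and
`linear_truth_config` makes the true %MVPA of each item's window an
exact linear function of age, gender and the integer item score.
Calibrating a linear-truth cohort from its latent truth recovers the
generating coefficients to numerical precision (1e-8 asserted); the
minute-realized path recovers them up to minute-grid quantization.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: no systematic (level-dependent) reporting
bias, no recall heaping or response styles; nonwear is placed
independently of activity, whereas real removals correlate with it
(sports, swimming); documented log labels are drawn independently of
the truth, so imputation is noisier than a diligent log; streams are
already minute-level EE/MVPA summaries, not raw sensor signals; no
within-week behavioural autocorrelation. Group-level accuracy results
on simulated cohorts therefore demonstrate correctness of the
machinery, not validity of any real instrument.

## 6. Numerical and I/O choices

- Validity and retention boundaries inclusive (≥ 0.70, ≥ 3, ≥ 1).
- pct_mvpa of a window with zero accounted minutes is NaN, and such
  occurrences are invalid (zero scheduled minutes likewise, audited).
- Encoding ties (equal criterion values) resolve to linear.
- Truncated-normal draws use rejection sampling with a clipped-mean
  fallback after 100 attempts (only reachable under extreme configs).
- All tabular I/O is comma-delimited UTF-8, one header row, preceded by
  `#` metadata lines (tool version, config hash, seed); timestamps are
  ISO-8601 local clock times with no timezone arithmetic, since school
  schedules are local by nature. Malformed rows are reported with
  their data-row number; missing required columns fail hard.
- Pipeline runs are byte-reproducible given config + seed; nothing
  time-dependent is written.

## 7. Problem sizes used in tests

Routine tests run cohorts of 40–150 participants; the law-of-large-
numbers check uses 2000; Monte Carlo checks use 200 replicates at n=500
per item (coefficient bias), 100 replicates per scenario (encoding
selection) and 2000 replicates at n=50 (TOST boundary size); the
acceptance script simulates 300 participants. These sizes were chosen
so each check's Monte Carlo error is small relative to its assertion
tolerance while the whole suite stays quick to run.

## 8. Known limitations

- Clipping predictions to [0, 100] (rather than modelling a bounded
  outcome) slightly biases predictions near the boundaries.
- Clipped measurement noise is not mean-zero for windows whose truth
  sits near 0 or 100 %MVPA; convergence checks use interior windows.
- The per-item models ignore measurement error in the criterion beyond
  averaging over occurrences (no regression-calibration/attenuation
  correction).
- Exact item prompts/anchors are placeholders; the scale is fixed to
  1–5 ordinal by default (configurable bounds).
- Individual-level prediction is intentionally out of scope as an
  accuracy claim: the method targets group-level inference, and the
  agreement reports quantify exactly that gap.
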