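"""Cross-validation and study-design statistics.

Three pieces: (1) individual- vs group-level percent-error agreement
summaries (group error is the mean of the signed individual errors, so
aggregation dilutes individual error); (2) equivalence testing of group
means by two one-sided tests (TOST) against a proportional region --
measures are declared equivalent when both one-sided 95% confidence
bounds of the mean paired difference fall inside +/- 10% (configurable)
of the accelerometer group mean; (3) sample-size calculation for the
incremental R^2 of the questionnaire score over age and gender in a
multiple regression, via the noncentral F distribution with Cohen's
f^2 = (R2_full - R2_reduced) / (1 - R2_full) and noncentrality n * f^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import calibrate as _cal
from . import screen as _scr
from . import segment as _seg


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Percent-error agreement between predicted and observed values.

    Individual error for participant i is
    ``(predicted_i - observed_i) / mean(observed) * 100``; the group
    error is the same formula applied to the group means and equals the
    mean of the individual errors.
    """

    n: int
    n_dropped: int
    individual_error_pct: np.ndarray
    min_error_pct: float
    max_error_pct: float
    mean_error_pct: float
    sd_error_pct: float
    mean_abs_error_pct: float
    group_error_pct: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_dropped": self.n_dropped,
            "min_error_pct": self.min_error_pct,
            "max_error_pct": self.max_error_pct,
            "mean_error_pct": self.mean_error_pct,
            "sd_error_pct": self.sd_error_pct,
            "mean_abs_error_pct": self.mean_abs_error_pct,
            "group_error_pct": self.group_error_pct,
        }


def agreement_report(predicted, observed) -> AgreementReport:
    """Individual and group percent-error summaries for paired vectors."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be the same length")
    keep = ~(np.isnan(pred) | np.isnan(obs))
    n_dropped = int((~keep).sum())
    pred, obs = pred[keep], obs[keep]
    if len(obs) < 2:
        raise ValueError("need at least 2 complete pairs")
    ref = obs.mean()
    if ref <= 0:
        raise ValueError("mean observed must be positive for percent errors")
    err = (pred - obs) / ref * 100.0
    return AgreementReport(
        n=len(err),
        n_dropped=n_dropped,
        individual_error_pct=err,
        min_error_pct=float(err.min()),
        max_error_pct=float(err.max()),
        mean_error_pct=float(err.mean()),
        sd_error_pct=float(err.std(ddof=1)),
        mean_abs_error_pct=float(np.abs(err).mean()),
        group_error_pct=float((pred.mean() - ref) / ref * 100.0),
    )


# ---------------------------------------------------------------------------
# equivalence (TOST)
# ---------------------------------------------------------------------------

@dataclass
class EquivalenceResult:
    """Two one-sided tests of the mean paired difference.

    ``equivalent`` iff both one-sided ``1 - alpha`` confidence bounds of
    the mean difference lie strictly inside the region
    ``+/- region_fraction * reference_mean`` (reference = observed
    accelerometer group mean).
    """

    n: int
    mean_difference: float
    reference_mean: float
    region_fraction: float
    region_half_width: float
    lower_bound: float
    upper_bound: float
    alpha: float
    equivalent: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["equivalent"] = bool(self.equivalent)
        return d


def tost_equivalence(
    predicted,
    observed,
    region_fraction: float = 0.10,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """TOST equivalence of paired measurements against a proportional region.

    Paired differences ``predicted - observed``; one-sided bounds
    ``mean +/- t_{1-alpha, n-1} * se``.  A zero-variance difference is
    handled exactly: the verdict follows from the constant difference.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be the same length")
    keep = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[keep], obs[keep]
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = pred - obs
    mean_diff = float(diff.mean())
    ref = float(obs.mean())
    margin = abs(region_fraction * ref)
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        lower = upper = mean_diff
    else:
        tcrit = stats.t.ppf(1 - alpha, n - 1)
        se = sd / np.sqrt(n)
        lower = mean_diff - tcrit * se
        upper = mean_diff + tcrit * se
    return EquivalenceResult(
        n=n,
        mean_difference=mean_diff,
        reference_mean=ref,
        region_fraction=region_fraction,
        region_half_width=margin,
        lower_bound=float(lower),
        upper_bound=float(upper),
        alpha=alpha,
        equivalent=bool(lower > -margin and upper < margin),
    )


# ---------------------------------------------------------------------------
# power / sample size for an R^2 increment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the incremental-R^2 F-test power calculation.

    Defaults: full model R^2 0.35 with 3 predictors (age, gender,
    questionnaire score), reduced model R^2 0.25, testing the single
    added predictor at alpha .05 and power .80.
    """

    r2_full: float = 0.35
    r2_reduced: float = 0.25
    n_predictors_full: int = 3
    n_tested_predictors: int = 1
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 <= self.r2_reduced < 1 or not 0 <= self.r2_full < 1:
            raise ValueError("R^2 values must lie in [0, 1)")
        if self.r2_full < self.r2_reduced:
            raise ValueError("r2_full must be >= r2_reduced")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_tested_predictors < 1 or (
            self.n_tested_predictors > self.n_predictors_full
        ):
            raise ValueError("invalid predictor counts")

    @property
    def f2(self) -> float:
        """Cohen's f^2 for the R^2 increment."""
        return (self.r2_full - self.r2_reduced) / (1.0 - self.r2_full)


def power_r2_change(n: int, spec: PowerSpec | None = None) -> float:
    """Power of the incremental-R^2 F test at sample size ``n``.

    Noncentral F with df1 = tested predictors, df2 = n - predictors - 1
    and noncentrality ``n * f^2``.
    """
    spec = spec or PowerSpec()
    df1 = spec.n_tested_predictors
    df2 = n - spec.n_predictors_full - 1
    if df2 < 1:
        return 0.0
    lam = n * spec.f2
    crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sample_size_r2_change(spec: PowerSpec | None = None, n_max: int = 100_000) -> int:
    """Smallest n whose incremental-R^2 F test reaches the target power."""
    spec = spec or PowerSpec()
    if spec.f2 == 0:
        raise ValueError(
            "r2_full equals r2_reduced: no finite sample size reaches the target"
        )
    n = spec.n_predictors_full + 2
    while n <= n_max:
        if power_r2_change(n, spec) >= spec.power:
            return n
        n += 1
    raise ValueError(f"required n exceeds {n_max}")


# ---------------------------------------------------------------------------
# hold-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    agreement: AgreementReport
    equivalence: EquivalenceResult
    n_train: int
    n_test: int
    n_test_evaluated: int
    models: dict = field(default_factory=dict, repr=False)


def holdout_cross_validate(
    cohort,
    split_fraction: float = 0.33,
    seed: int = 0,
    rules: _scr.ScreeningRules | None = None,
    encoding: str = "auto",
    region_fraction: float = 0.10,
    alpha: float = 0.05,
    min_obs_per_coef: int = 5,
) -> CrossValidationResult:
    """Fit calibration models on a training split, evaluate held out.

    ``split_fraction`` is the held-out share of participants; the split
    is deterministic given ``seed``.  Held-out participants contribute
    when every activity window type has at least one valid occurrence,
    so predicted and observed weekly minutes cover the same windows.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")
    rules = rules or _scr.ScreeningRules()
    rng = np.random.default_rng(seed)
    pids = list(cohort.participants["participant_id"])
    n_test = max(1, int(round(split_fraction * len(pids))))
    test_ids = set(rng.choice(pids, size=n_test, replace=False))
    train_ids = [p for p in pids if p not in test_ids]

    windows = _seg.build_weekly_windows(cohort.schedule, cohort.week)
    summaries = _seg.segment_cohort_streams(cohort.streams, windows)
    summaries, _ = _scr.impute_nonwear(
        summaries, cohort.streams, cohort.logs, cohort.met_table
    )
    summaries = _scr.flag_valid_windows(summaries, rules)

    train_sum = summaries[summaries["participant_id"].isin(train_ids)]
    retention = _scr.retain_participants(train_sum, rules)
    data, _ = _cal.assemble_dataset(
        train_sum, cohort.responses, cohort.participants, cohort.instrument, retention
    )
    models = _cal.fit_all_items(
        data, cohort.instrument, encoding=encoding, min_obs_per_coef=min_obs_per_coef
    )

    winfo = _cal.window_frequencies(windows)
    test_resp = cohort.responses[cohort.responses["participant_id"].isin(test_ids)]
    _, composites = _cal.predict_composites(
        models, test_resp, cohort.participants, winfo, cohort.instrument
    )
    test_sum = summaries[summaries["participant_id"].isin(test_ids)]
    observed = _cal.observed_weekly_minutes(test_sum, winfo, cohort.instrument)
    merged = composites.merge(observed, on="participant_id", how="inner")
    if len(merged) < 3:
        raise ValueError("too few evaluable held-out participants")
    report = agreement_report(merged["weekly_min_week"], merged["observed_min_week"])
    eq = tost_equivalence(
        merged["weekly_min_week"], merged["observed_min_week"],
        region_fraction=region_fraction, alpha=alpha,
    )
    return CrossValidationResult(
        agreement=report,
        equivalence=eq,
        n_train=len(train_ids),
        n_test=n_test,
        n_test_evaluated=len(merged),
        models=models,
    )
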