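"""Compliance screening and documented-nonwear MET imputation.

A window occurrence counts as valid when worn + imputed minutes cover at
least 70% of its scheduled minutes (inclusive; "at least" taken
literally).  A participant enters an item's calibration when the item's
window type has at least 3 valid occurrences over the week -- except PE,
Saturday and Sunday, which occur at most a few times per week and only
need 1.  Two screening modes are supported: ``item_wise`` retains a
participant per window type, the traditional ``whole_week`` mode keeps a
participant only when every window type passes, so the item-wise
retained set always contains the whole-week one.

Documented nonwear bouts from participant activity logs are imputed by
assigning the logged activity's compendium MET value to nonwear minutes
the bout covers; imputed minutes count toward both the validity fraction
and %MVPA (imputation exists to maximize the usable sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as date_type

import numpy as np
import pandas as pd

from .segment import MVPA_MET_THRESHOLD, AccelStream, WindowType

logger = logging.getLogger(__name__)

DEFAULT_EXCEPTION_WINDOWS = frozenset(
    {WindowType.PHYSICAL_EDUCATION, WindowType.SATURDAY, WindowType.SUNDAY}
)

DEFAULT_MET_TABLE = {
    # small testing lookup; real analyses supply their own compendium extract
    "walking": 3.5,
    "bicycling": 6.8,
    "basketball": 6.5,
    "soccer": 7.0,
    "swimming": 6.0,
    "dance": 4.5,
    "tv_watching": 1.3,
    "reading": 1.3,
    "video_games": 1.5,
    "homework": 1.5,
}


@dataclass(frozen=True)
class ScreeningRules:
    """Wear-compliance thresholds; defaults follow the 70% / 3-period rule."""

    min_valid_fraction: float = 0.70
    min_valid_periods: int = 3
    exception_windows: frozenset = DEFAULT_EXCEPTION_WINDOWS
    exception_min_periods: int = 1
    mode: str = "item_wise"  # or "whole_week"

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.min_valid_periods < 1 or self.exception_min_periods < 1:
            raise ValueError("minimum valid periods must be >= 1")
        if self.mode not in ("item_wise", "whole_week"):
            raise ValueError(f"unknown screening mode {self.mode!r}")
        object.__setattr__(
            self,
            "exception_windows",
            frozenset(WindowType(w) for w in self.exception_windows),
        )

    def required_periods(self, window_type) -> int:
        wt = WindowType(window_type)
        if wt in self.exception_windows:
            return self.exception_min_periods
        return self.min_valid_periods


@dataclass
class NonwearLogEntry:
    """One documented nonwear bout from a participant's daily activity log."""

    participant_id: str
    date: date_type
    start: pd.Timestamp
    end: pd.Timestamp
    activity: str
    met_value: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"log entry {self.participant_id} {self.date}: start not before end"
            )


@dataclass
class ImputationAudit:
    """Record of imputation decisions, including skipped log entries."""

    imputed_minutes: int = 0
    skipped_activities: list[str] = field(default_factory=list)
    invalid_reasons: dict = field(default_factory=dict)


def impute_nonwear(
    summaries: pd.DataFrame,
    streams: dict[str, AccelStream],
    log_entries: pd.DataFrame,
    met_table: dict[str, float] | None = None,
    mvpa_threshold: float = MVPA_MET_THRESHOLD,
) -> tuple[pd.DataFrame, ImputationAudit]:
    """Impute compendium MET values into documented nonwear minutes.

    For each window occurrence, nonwear minutes covered by a log entry
    of the same participant/date receive the logged activity's MET value
    (first covering entry wins); minutes at/above ``mvpa_threshold``
    count as MVPA.  Worn minutes are never altered.  ``pct_mvpa`` is
    recomputed over worn + imputed minutes.  Log activities missing from
    ``met_table`` are skipped with a warning and recorded in the audit.
    """
    met_table = dict(DEFAULT_MET_TABLE if met_table is None else met_table)
    audit = ImputationAudit()
    out = summaries.copy()
    if log_entries is None or len(log_entries) == 0:
        return out, audit

    logs = log_entries.copy()
    logs["date"] = pd.to_datetime(logs["date"]).dt.date
    logs["start"] = pd.to_datetime(logs["start"])
    logs["end"] = pd.to_datetime(logs["end"])
    by_pid_date = {k: g for k, g in logs.groupby(["participant_id", "date"])}

    imputed = np.zeros(len(out), dtype=int)
    imputed_mvpa = np.zeros(len(out), dtype=int)
    for idx, row in enumerate(out.itertuples()):
        key = (row.participant_id, _as_date(row.date))
        entries = by_pid_date.get(key)
        if entries is None:
            continue
        stream = streams.get(row.participant_id)
        if stream is None or len(stream.records) == 0:
            continue
        rec = stream.records
        ts = rec["timestamp"].to_numpy()
        i0 = np.searchsorted(ts, np.datetime64(row.start), side="left")
        i1 = np.searchsorted(ts, np.datetime64(row.end), side="left")
        if i1 <= i0:
            continue
        win_ts = ts[i0:i1]
        nonwear = rec["wear"].to_numpy()[i0:i1] == 0
        assigned_met = np.full(i1 - i0, np.nan)
        for entry in entries.itertuples():
            met = met_table.get(entry.activity)
            if met is None:
                if entry.activity not in audit.skipped_activities:
                    logger.warning(
                        "activity %r absent from MET table; log entry skipped",
                        entry.activity,
                    )
                    audit.skipped_activities.append(entry.activity)
                continue
            covered = (
                (win_ts >= np.datetime64(entry.start))
                & (win_ts < np.datetime64(entry.end))
                & nonwear
                & np.isnan(assigned_met)
            )
            assigned_met[covered] = met
        n_imp = int((~np.isnan(assigned_met)).sum())
        if n_imp == 0:
            continue
        imputed[idx] = n_imp
        imputed_mvpa[idx] = int(np.nansum(assigned_met >= mvpa_threshold))
        audit.imputed_minutes += n_imp

    out["imputed_minutes"] = imputed
    out["imputed_mvpa_minutes"] = imputed_mvpa
    accounted = out["worn_minutes"] + out["imputed_minutes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_mvpa"] = np.where(
            accounted > 0,
            100.0 * (out["mvpa_minutes"] + out["imputed_mvpa_minutes"]) / accounted,
            np.nan,
        )
    return out, audit


def _as_date(value) -> date_type:
    if isinstance(value, date_type):
        return value
    return pd.Timestamp(value).date()


def flag_valid_windows(
    summaries: pd.DataFrame, rules: ScreeningRules | None = None
) -> pd.DataFrame:
    """Set ``valid`` per window occurrence: accounted/scheduled >= threshold.

    Accounted minutes are worn + imputed.  Occurrences with zero
    scheduled minutes are invalid (audited via the fraction being NaN).
    """
    rules = rules or ScreeningRules()
    out = summaries.copy()
    sched = out["scheduled_minutes"].to_numpy(dtype=float)
    accounted = (out["worn_minutes"] + out["imputed_minutes"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sched > 0, accounted / sched, np.nan)
    out["accounted_fraction"] = frac
    out["valid"] = (sched > 0) & (frac >= rules.min_valid_fraction)
    return out


def retain_participants(
    summaries: pd.DataFrame, rules: ScreeningRules | None = None
) -> pd.DataFrame:
    """Per (participant, window_type) inclusion decisions.

    ``item_wise``: a participant enters a window type's calibration iff
    that type has >= the required number of valid occurrences (1 for the
    exception windows, otherwise ``min_valid_periods``).  ``whole_week``:
    the participant is retained for every window type iff all scheduled
    window types meet their requirement.

    Returns a frame with columns ``participant_id, window_type, n_valid,
    required, retained``.
    """
    rules = rules or ScreeningRules()
    if "valid" not in summaries.columns or summaries["valid"].isna().any():
        raise ValueError("summaries must be passed through flag_valid_windows first")
    counts = (
        summaries.groupby(["participant_id", "window_type"], sort=True)["valid"]
        .sum()
        .astype(int)
        .reset_index(name="n_valid")
    )
    counts["required"] = counts["window_type"].map(rules.required_periods)
    counts["meets"] = counts["n_valid"] >= counts["required"]
    if rules.mode == "item_wise":
        counts["retained"] = counts["meets"]
    else:
        all_ok = counts.groupby("participant_id")["meets"].transform("all")
        counts["retained"] = all_ok
    return counts.drop(columns="meets")


def retained_set(retention: pd.DataFrame, window_type) -> set[str]:
    """Participant ids retained for one window type."""
    wt = WindowType(window_type).value
    mask = (retention["window_type"] == wt) & retention["retained"]
    return set(retention.loc[mask, "participant_id"])
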