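"""Map minute-level accelerometer streams onto a segmented weekly schedule.

A school week is carved into ten recall-matched window types: four
anchored to each school's start/end clock times (before-school,
commutes, after-school), three supplied per date by the school (recess,
PE, lunch), a fixed evening block (18:00-22:00), and one whole-day
window per weekend day (07:00-22:00).  Minute records are assigned to
windows with half-open ``[start, end)`` intervals, each minute labelled
by its interval start, so no minute can land in two windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from enum import Enum

import numpy as np
import pandas as pd

MVPA_MET_THRESHOLD = 3.0  # conventional moderate-intensity cut, config-overridable


class WindowType(str, Enum):
    BEFORE_SCHOOL = "before_school"
    TRANSPORT_TO_SCHOOL = "transport_to_school"
    RECESS = "recess"
    PHYSICAL_EDUCATION = "physical_education"
    LUNCH = "lunch"
    TRANSPORT_FROM_SCHOOL = "transport_from_school"
    AFTER_SCHOOL = "after_school"
    EVENING = "evening"
    SATURDAY = "saturday"
    SUNDAY = "sunday"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Window types supplied per date by the school rather than derived.
PROVIDED_WINDOWS = frozenset(
    {WindowType.RECESS, WindowType.PHYSICAL_EDUCATION, WindowType.LUNCH}
)
WEEKEND_WINDOWS = frozenset({WindowType.SATURDAY, WindowType.SUNDAY})


class ScheduleError(ValueError):
    """Raised for inconsistent schedule configurations."""


def _parse_time(value) -> time:
    if isinstance(value, time):
        return value
    if isinstance(value, str):
        parts = value.strip().split(":")
        return time(int(parts[0]), int(parts[1]) if len(parts) > 1 else 0)
    raise ScheduleError(f"cannot parse clock time from {value!r}")


@dataclass
class ScheduleConfig:
    """School clock times plus per-date provided windows.

    ``special_windows`` maps date -> {window_type: (start, end)} for
    recess, PE and lunch; dates without an entry simply have no such
    window that day.  Derived bounds: the commute to school occupies the
    30 min before school start, before-school the 60 min before that;
    the commute home occupies the 30 min after school end, after-school
    runs from there to 18:00.
    """

    school_start: time = time(8, 15)
    school_end: time = time(15, 30)
    special_windows: dict[date, dict[WindowType, tuple[time, time]]] = field(
        default_factory=dict
    )
    evening_bounds: tuple[time, time] = (time(18, 0), time(22, 0))
    weekend_bounds: tuple[time, time] = (time(7, 0), time(22, 0))
    transport_minutes: int = 30
    before_school_minutes: int = 60

    def __post_init__(self) -> None:
        self.school_start = _parse_time(self.school_start)
        self.school_end = _parse_time(self.school_end)
        self.evening_bounds = tuple(_parse_time(t) for t in self.evening_bounds)
        self.weekend_bounds = tuple(_parse_time(t) for t in self.weekend_bounds)
        cleaned: dict[date, dict[WindowType, tuple[time, time]]] = {}
        for d, wins in self.special_windows.items():
            if isinstance(d, str):
                d = date.fromisoformat(d)
            cleaned[d] = {}
            for wt, (s, e) in wins.items():
                wt = WindowType(wt)
                if wt not in PROVIDED_WINDOWS:
                    raise ScheduleError(
                        f"{wt.value} is not a school-provided window type"
                    )
                s, e = _parse_time(s), _parse_time(e)
                if s >= e:
                    raise ScheduleError(
                        f"{wt.value} on {d}: start {s} not before end {e}"
                    )
                cleaned[d][wt] = (s, e)
        self.special_windows = cleaned
        if self.school_start >= self.school_end:
            raise ScheduleError("school_start must precede school_end")


def week_dates(monday: date) -> list[date]:
    """The 7 dates Monday..Sunday of the week starting at ``monday``."""
    if isinstance(monday, str):
        monday = date.fromisoformat(monday)
    if monday.weekday() != 0:
        raise ScheduleError(f"{monday} is not a Monday")
    return [monday + timedelta(days=i) for i in range(7)]


def _dt(d: date, t: time) -> datetime:
    return datetime.combine(d, t)


WINDOW_COLUMNS = ["window_type", "date", "start", "end", "scheduled_minutes"]


def build_weekly_windows(schedule: ScheduleConfig, dates) -> pd.DataFrame:
    """Materialize the weekly window table for the given dates.

    Weekdays yield the eight weekday window types (recess/PE/lunch only
    on dates with provided times); Saturday/Sunday yield one whole-day
    window each.  Raises :class:`ScheduleError` when any two windows on
    the same date overlap.
    """
    rows: list[dict] = []
    for d in dates:
        if isinstance(d, str):
            d = date.fromisoformat(d)
        if d.weekday() >= 5:
            wt = WindowType.SATURDAY if d.weekday() == 5 else WindowType.SUNDAY
            ws, we = schedule.weekend_bounds
            rows.append(_row(wt, d, _dt(d, ws), _dt(d, we)))
            continue
        trans_to_start = _dt(d, schedule.school_start) - timedelta(
            minutes=schedule.transport_minutes
        )
        before_start = trans_to_start - timedelta(minutes=schedule.before_school_minutes)
        rows.append(_row(WindowType.BEFORE_SCHOOL, d, before_start, trans_to_start))
        rows.append(
            _row(WindowType.TRANSPORT_TO_SCHOOL, d, trans_to_start,
                 _dt(d, schedule.school_start))
        )
        trans_from_end = _dt(d, schedule.school_end) + timedelta(
            minutes=schedule.transport_minutes
        )
        rows.append(
            _row(WindowType.TRANSPORT_FROM_SCHOOL, d, _dt(d, schedule.school_end),
                 trans_from_end)
        )
        evening_start = _dt(d, schedule.evening_bounds[0])
        if trans_from_end < evening_start:
            rows.append(_row(WindowType.AFTER_SCHOOL, d, trans_from_end, evening_start))
        rows.append(
            _row(WindowType.EVENING, d, evening_start,
                 _dt(d, schedule.evening_bounds[1]))
        )
        for wt, (s, e) in schedule.special_windows.get(d, {}).items():
            rows.append(_row(wt, d, _dt(d, s), _dt(d, e)))

    windows = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    _check_overlaps(windows)
    return windows.sort_values(["date", "start"], kind="stable").reset_index(drop=True)


def _row(wt: WindowType, d: date, start: datetime, end: datetime) -> dict:
    if start >= end:
        raise ScheduleError(f"{wt.value} on {d}: start {start} not before end {end}")
    return {
        "window_type": wt.value,
        "date": d,
        "start": pd.Timestamp(start),
        "end": pd.Timestamp(end),
        "scheduled_minutes": int((end - start).total_seconds() // 60),
    }


def _check_overlaps(windows: pd.DataFrame) -> None:
    clashes = []
    for d, grp in windows.groupby("date"):
        grp = grp.sort_values("start")
        prev = None
        for rec in grp.itertuples():
            if prev is not None and rec.start < prev.end:
                clashes.append(
                    f"{d}: {prev.window_type} [{prev.start.time()}-{prev.end.time()}) "
                    f"overlaps {rec.window_type} [{rec.start.time()}-{rec.end.time()})"
                )
            prev = rec
    if clashes:
        raise ScheduleError("overlapping windows: " + "; ".join(clashes))


@dataclass
class AccelStream:
    """One participant's minute-level record.

    ``records`` columns: ``timestamp`` (minute resolution, strictly
    increasing), ``ee_mets`` (>= 0), ``wear`` (0/1) and ``mvpa`` (0/1).
    When ``mvpa`` is absent it is derived as ``ee_mets >= threshold``
    on worn minutes.
    """

    participant_id: str
    records: pd.DataFrame

    @classmethod
    def from_frame(
        cls,
        participant_id: str,
        records: pd.DataFrame,
        mvpa_threshold: float = MVPA_MET_THRESHOLD,
    ) -> "AccelStream":
        rec = records.copy()
        rec["timestamp"] = pd.to_datetime(rec["timestamp"])
        if len(rec):
            diffs = rec["timestamp"].diff().dropna()
            if (diffs <= pd.Timedelta(0)).any():
                raise ValueError(
                    f"{participant_id}: timestamps not strictly increasing"
                )
            same_day = rec["timestamp"].dt.normalize().diff().dropna() == pd.Timedelta(0)
            if (diffs[same_day.values] != pd.Timedelta(minutes=1)).any():
                raise ValueError(
                    f"{participant_id}: within-day timestamps not 1-min spaced"
                )
        if (rec["ee_mets"] < 0).any():
            raise ValueError(f"{participant_id}: negative energy expenditure")
        rec["wear"] = rec["wear"].astype(np.int8)
        if "mvpa" not in rec.columns:
            rec["mvpa"] = (rec["ee_mets"] >= mvpa_threshold).astype(np.int8)
        else:
            rec["mvpa"] = rec["mvpa"].astype(np.int8)
        return cls(participant_id=participant_id, records=rec)


SUMMARY_COLUMNS = [
    "participant_id", "window_type", "date", "start", "end",
    "scheduled_minutes", "worn_minutes", "mvpa_minutes",
    "imputed_minutes", "imputed_mvpa_minutes", "pct_mvpa", "valid",
]


def segment_stream(stream: AccelStream, windows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate one stream into per-window summaries (pre-screening).

    Each minute joins at most one window (half-open intervals, validated
    non-overlapping).  ``pct_mvpa`` is computed over worn minutes only at
    this stage; imputation and validity flags come later.  An empty
    stream yields all windows with zero worn minutes; a non-empty stream
    that does not overlap the week at all is an error.
    """
    rec = stream.records
    if len(rec):
        week_start = windows["start"].min()
        week_end = windows["end"].max()
        ts = rec["timestamp"]
        if ts.iloc[-1] < week_start or ts.iloc[0] >= week_end:
            raise ValueError(
                f"{stream.participant_id}: stream "
                f"[{ts.iloc[0]}..{ts.iloc[-1]}] does not overlap the scheduled "
                f"week [{week_start}..{week_end})"
            )
        ts_np = ts.to_numpy()
        wear = rec["wear"].to_numpy()
        mvpa = rec["mvpa"].to_numpy()
    rows = []
    for win in windows.itertuples():
        worn = 0
        mv = 0
        if len(rec):
            i0 = np.searchsorted(ts_np, np.datetime64(win.start), side="left")
            i1 = np.searchsorted(ts_np, np.datetime64(win.end), side="left")
            if i1 > i0:
                w = wear[i0:i1]
                worn = int(w.sum())
                mv = int((w & mvpa[i0:i1]).sum())
        rows.append(
            {
                "participant_id": stream.participant_id,
                "window_type": win.window_type,
                "date": win.date,
                "start": win.start,
                "end": win.end,
                "scheduled_minutes": win.scheduled_minutes,
                "worn_minutes": worn,
                "mvpa_minutes": mv,
                "imputed_minutes": 0,
                "imputed_mvpa_minutes": 0,
                "pct_mvpa": 100.0 * mv / worn if worn else np.nan,
                "valid": pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def segment_cohort_streams(
    streams: dict[str, AccelStream], windows: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate :func:`segment_stream` over a cohort's streams."""
    parts = [segment_stream(s, windows) for s in streams.values()]
    if not parts:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(parts, ignore_index=True)
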