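import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from yapcal import screen as scr
from yapcal import segment as seg
from yapcal import simulate as sim
from yapcal.instrument import default_instrument

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def paper_cohort():
    """A small realistic cohort shared across tests."""
    return sim.simulate_cohort(sim.paper_like_config(80, seed=7))


@pytest.fixture(scope="session")
def screened_paper_cohort(paper_cohort):
    """(cohort, windows, flagged summaries) after imputation + validity flags."""
    windows = seg.build_weekly_windows(paper_cohort.schedule, paper_cohort.week)
    summaries = seg.segment_cohort_streams(paper_cohort.streams, windows)
    imputed, _ = scr.impute_nonwear(
        summaries, paper_cohort.streams, paper_cohort.logs, paper_cohort.met_table
    )
    return paper_cohort, windows, scr.flag_valid_windows(imputed)


@pytest.fixture(scope="session")
def linear_cohort():
    """Noiseless cohort whose truth is exactly linear in (age, gender, score)."""
    return sim.simulate_cohort(sim.linear_truth_config(120, seed=5))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_segment(stream: seg.AccelStream, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-minute double loop over (minute, window); asserts the partition
    property (no minute claimed by two windows) along the way."""
    counts = {
        (w.window_type, w.date): {"worn": 0, "mvpa": 0}
        for w in windows.itertuples()
    }
    for rec in stream.records.itertuples():
        hits = []
        for w in windows.itertuples():
            if w.start <= rec.timestamp < w.end:
                hits.append((w.window_type, w.date))
        assert len(hits) <= 1, f"minute {rec.timestamp} in two windows: {hits}"
        if hits and rec.wear:
            counts[hits[0]]["worn"] += 1
            if rec.mvpa:
                counts[hits[0]]["mvpa"] += 1
    rows = []
    for w in windows.itertuples():
        c = counts[(w.window_type, w.date)]
        rows.append(
            {
                "window_type": w.window_type,
                "date": w.date,
                "worn_minutes": c["worn"],
                "mvpa_minutes": c["mvpa"],
                "pct_mvpa": 100.0 * c["mvpa"] / c["worn"] if c["worn"] else np.nan,
            }
        )
    return pd.DataFrame(rows)


def random_schedule(rng) -> tuple[seg.ScheduleConfig, list]:
    """A random but internally consistent weekly schedule."""
    from datetime import date, time

    start_h, start_m = 7, int(rng.integers(30, 60))
    end_h, end_m = 14 + int(rng.integers(0, 2)), int(rng.integers(0, 60))
    week = seg.week_dates(date(2015, 3, 9))
    special = {}
    for d in week[:5]:
        wins = {
            seg.WindowType.RECESS: (
                time(10, int(rng.integers(0, 15))),
                time(10, int(rng.integers(20, 40))),
            ),
            seg.WindowType.LUNCH: (
                time(12, int(rng.integers(0, 15))),
                time(12, int(rng.integers(20, 55))),
            ),
        }
        if rng.random() < 0.6:
            wins[seg.WindowType.PHYSICAL_EDUCATION] = (
                time(13, int(rng.integers(0, 15))),
                time(13, int(rng.integers(20, 59))),
            )
        special[d] = wins
    schedule = seg.ScheduleConfig(
        school_start=time(start_h, start_m),
        school_end=time(end_h, end_m),
        special_windows=special,
    )
    return schedule, week


def random_stream(rng, week, pid="PX", n_days=3) -> seg.AccelStream:
    """Random wear/MVPA minutes over a few random days of the week."""
    days = sorted(rng.choice(7, size=n_days, replace=False))
    frames = []
    for d in days:
        day = pd.Timestamp(week[d])
        start = day + pd.Timedelta(hours=6, minutes=int(rng.integers(0, 60)))
        n_min = int(rng.integers(300, 960))
        ts = pd.date_range(start, periods=n_min, freq="min")
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "ee_mets": rng.uniform(1, 8, n_min).round(2),
                    "wear": rng.integers(0, 2, n_min),
                    "mvpa": rng.integers(0, 2, n_min),
                }
            )
        )
    return seg.AccelStream.from_frame(pid, pd.concat(frames, ignore_index=True))
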