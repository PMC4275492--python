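from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from yapcal import screen as scr
from yapcal import segment as seg

D = date(2015, 3, 9)


def _summary(pid="P1", wt="evening", d=D, sched=240, worn=0, mvpa=0,
             start="2015-03-09 18:00"):
    start = pd.Timestamp(start)
    return {
        "participant_id": pid, "window_type": wt, "date": d,
        "start": start, "end": start + pd.Timedelta(minutes=sched),
        "scheduled_minutes": sched, "worn_minutes": worn, "mvpa_minutes": mvpa,
        "imputed_minutes": 0, "imputed_mvpa_minutes": 0,
        "pct_mvpa": 100.0 * mvpa / worn if worn else np.nan, "valid": pd.NA,
    }


def _stream_with_gap(pid="P1", start="2015-03-09 18:00", n=240, gap=(60, 90)):
    ts = pd.date_range(start, periods=n, freq="min")
    wear = np.ones(n, dtype=int)
    wear[gap[0]:gap[1]] = 0
    return seg.AccelStream.from_frame(
        pid,
        pd.DataFrame({"timestamp": ts, "ee_mets": np.where(wear, 2.0, 0.0),
                      "wear": wear, "mvpa": 0}),
    )


def test_no_log_entries_leaves_summary_unchanged():
    summaries = pd.DataFrame([_summary(worn=100, mvpa=20)])
    out, audit = scr.impute_nonwear(summaries, {}, pd.DataFrame(), None)
    pd.testing.assert_frame_equal(out, summaries)
    assert audit.imputed_minutes == 0


def test_fully_logged_active_gap_imputes_as_mvpa():
    """A 30-min nonwear gap covered by a logged activity at >= 3 METs adds
    30 imputed minutes, all counting as MVPA; worn minutes unchanged."""
    stream = _stream_with_gap(gap=(60, 90))
    summaries = pd.DataFrame([_summary(sched=240, worn=210, mvpa=0)])
    logs = pd.DataFrame([
        {"participant_id": "P1", "date": D,
         "start": pd.Timestamp("2015-03-09 18:30"),
         "end": pd.Timestamp("2015-03-09 20:00"), "activity": "basketball"}
    ])
    out, audit = scr.impute_nonwear(summaries, {"P1": stream}, logs)
    row = out.iloc[0]
    assert row["imputed_minutes"] == 30
    assert row["imputed_mvpa_minutes"] == 30
    assert row["worn_minutes"] == 210
    assert row["pct_mvpa"] == pytest.approx(100.0 * 30 / 240)
    assert audit.imputed_minutes == 30


def test_sedentary_logged_gap_imputes_without_mvpa():
    stream = _stream_with_gap(gap=(0, 240))
    summaries = pd.DataFrame([_summary(sched=240, worn=0, mvpa=0)])
    logs = pd.DataFrame([
        {"participant_id": "P1", "date": D,
         "start": pd.Timestamp("2015-03-09 18:00"),
         "end": pd.Timestamp("2015-03-09 22:00"), "activity": "tv_watching"}
    ])
    out, _ = scr.impute_nonwear(summaries, {"P1": stream}, logs)
    assert out.iloc[0]["imputed_minutes"] == 240
    assert out.iloc[0]["imputed_mvpa_minutes"] == 0
    assert out.iloc[0]["pct_mvpa"] == 0.0


def test_unknown_activity_skipped_and_audited():
    stream = _stream_with_gap()
    summaries = pd.DataFrame([_summary(sched=240, worn=210)])
    logs = pd.DataFrame([
        {"participant_id": "P1", "date": D,
         "start": pd.Timestamp("2015-03-09 18:00"),
         "end": pd.Timestamp("2015-03-09 22:00"), "activity": "spelunking"}
    ])
    out, audit = scr.impute_nonwear(summaries, {"P1": stream}, logs)
    assert out.iloc[0]["imputed_minutes"] == 0
    assert audit.skipped_activities == ["spelunking"]


def test_imputation_conserves_worn_minutes_and_matches_minute_oracle():
    """Random gaps/logs: imputed pct_mvpa equals a per-minute brute-force
    overlap computation, and worn minutes never change."""
    rng = np.random.default_rng(3)
    met_table = dict(scr.DEFAULT_MET_TABLE)
    labels = list(met_table) + ["unknown_sport"]
    for rep in range(10):
        n = 240
        wear = (rng.random(n) < 0.7).astype(int)
        ts = pd.date_range("2015-03-09 18:00", periods=n, freq="min")
        stream = seg.AccelStream.from_frame(
            "P1", pd.DataFrame({
                "timestamp": ts, "ee_mets": np.where(wear, 4.0, 0.0),
                "wear": wear, "mvpa": wear,
            }),
        )
        summaries = pd.DataFrame([
            _summary(sched=n, worn=int(wear.sum()), mvpa=int(wear.sum()))
        ])
        entries = []
        for _ in range(rng.integers(1, 5)):
            a, b = sorted(rng.integers(0, n, size=2))
            if a == b:
                continue
            entries.append({
                "participant_id": "P1", "date": D,
                "start": ts[a], "end": ts[a] + pd.Timedelta(minutes=int(b - a)),
                "activity": labels[rng.integers(len(labels))],
            })
        logs = pd.DataFrame(entries)
        out, _ = scr.impute_nonwear(summaries, {"P1": stream}, logs, met_table)

        # brute force on the minute grid: first covering known entry wins
        imp = imp_mvpa = 0
        for i in range(n):
            if wear[i]:
                continue
            for e in entries:
                met = met_table.get(e["activity"])
                if met is None:
                    continue
                if e["start"] <= ts[i] < e["end"]:
                    imp += 1
                    imp_mvpa += met >= 3.0
                    break
        row = out.iloc[0]
        assert row["worn_minutes"] == int(wear.sum())
        assert row["imputed_minutes"] == imp
        assert row["imputed_mvpa_minutes"] == imp_mvpa
        expected_pct = 100.0 * (wear.sum() + imp_mvpa) / (wear.sum() + imp)
        assert row["pct_mvpa"] == pytest.approx(expected_pct)


@pytest.mark.parametrize(
    "worn,imputed,sched,expect",
    [
        (180, 0, 240, True),    # 75% -> valid
        (148, 20, 240, True),   # exactly 70% (inclusive boundary)
        (167, 0, 240, False),   # just below 70%
        (0, 0, 240, False),
        (10, 0, 0, False),      # zero scheduled minutes -> invalid
    ],
)
def test_validity_fraction_boundaries(worn, imputed, sched, expect):
    df = pd.DataFrame([_summary(sched=sched, worn=worn)])
    df["imputed_minutes"] = imputed
    out = scr.flag_valid_windows(df)
    assert bool(out["valid"].iloc[0]) is expect


def _retention_fixture():
    """Participant A: 3 valid evenings + 1 valid PE; participant B: valid
    evenings only; all other occurrences invalid."""
    rows = []
    for pid in ("A", "B"):
        for i in range(7):
            d = date(2015, 3, 9 + i)
            rows.append(_summary(pid, "evening", d, worn=240 if i < 3 or pid == "B" else 0))
        rows.append(_summary(pid, "physical_education", D, sched=45,
                             worn=45 if pid == "A" else 0))
        rows.append(_summary(pid, "saturday", date(2015, 3, 14), sched=900, worn=0))
    return scr.flag_valid_windows(pd.DataFrame(rows))


def test_item_wise_retention_with_pe_exception():
    flagged = _retention_fixture()
    ret = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    get = lambda pid, wt: ret[(ret["participant_id"] == pid) & (ret["window_type"] == wt)]["retained"].iloc[0]
    assert get("A", "evening")
    assert get("A", "physical_education")  # 1 valid PE suffices (exception)
    assert not get("A", "saturday")
    assert get("B", "evening")
    assert not get("B", "physical_education")


def test_whole_week_excludes_evening_only_participant():
    """A participant with data only in evenings survives item-wise screening
    for the evening item but is excluded entirely under whole-week rules."""
    flagged = _retention_fixture()
    ww = scr.retain_participants(flagged, scr.ScreeningRules(mode="whole_week"))
    assert not ww[ww["participant_id"] == "B"]["retained"].any()
    iw = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    assert iw[(iw["participant_id"] == "B") & (iw["window_type"] == "evening")]["retained"].iloc[0]


def test_modes_agree_when_everything_is_valid():
    rows = []
    for wt, sched in [("evening", 240), ("physical_education", 45), ("saturday", 900)]:
        for i in range(3):
            rows.append(_summary("A", wt, date(2015, 3, 9 + i), sched=sched, worn=sched))
    flagged = scr.flag_valid_windows(pd.DataFrame(rows))
    iw = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    ww = scr.retain_participants(flagged, scr.ScreeningRules(mode="whole_week"))
    assert iw["retained"].all() and ww["retained"].all()


def test_item_wise_retention_dominates_whole_week(screened_paper_cohort):
    """On a simulated cohort, every window type's item-wise retained set
    contains the whole-week retained set."""
    _, _, flagged = screened_paper_cohort
    iw = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    ww = scr.retain_participants(flagged, scr.ScreeningRules(mode="whole_week"))
    for wt in flagged["window_type"].unique():
        assert scr.retained_set(ww, wt) <= scr.retained_set(iw, wt)


@given(
    frac=st.floats(0.4, 0.99),
    periods=st.integers(1, 5),
)
def test_retention_monotone_in_thresholds(screened_paper_cohort, frac, periods):
    """Lowering the validity fraction or the required period count never
    shrinks any retained set."""
    _, _, flagged = screened_paper_cohort
    strict = scr.retain_participants(
        scr.flag_valid_windows(flagged, scr.ScreeningRules(min_valid_fraction=frac)),
        scr.ScreeningRules(min_valid_fraction=frac, min_valid_periods=periods),
    )
    lax = scr.retain_participants(
        scr.flag_valid_windows(flagged, scr.ScreeningRules(min_valid_fraction=max(frac - 0.2, 0.05))),
        scr.ScreeningRules(min_valid_fraction=max(frac - 0.2, 0.05),
                           min_valid_periods=max(periods - 1, 1)),
    )
    for wt in flagged["window_type"].unique():
        assert scr.retained_set(strict, wt) <= scr.retained_set(lax, wt)


def test_rules_validation():
    with pytest.raises(ValueError):
        scr.ScreeningRules(min_valid_fraction=0.0)
    with pytest.raises(ValueError):
        scr.ScreeningRules(min_valid_periods=0)
    with pytest.raises(ValueError):
        scr.ScreeningRules(mode="per_item")
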