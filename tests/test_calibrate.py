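import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from yapcal import calibrate as cal
from yapcal import screen as scr
from yapcal import segment as seg
from yapcal import simulate as sim


def _make_dataset(rng, n=300, coefs=(10.0, 1.2, 4.0, 6.0), noise_sd=0.0,
                  item_id="act_evening", score_means=None):
    """Synthetic calibration rows; linear truth unless score_means given."""
    age = rng.uniform(8, 18, n)
    gender = rng.integers(0, 2, n).astype(float)
    score = rng.integers(1, 6, n).astype(float)
    if score_means is None:
        b0, b1, b2, b3 = coefs
        y = b0 + b1 * age + b2 * gender + b3 * score
    else:
        b0, b1, b2, _ = coefs
        y = b0 + b1 * age + b2 * gender + np.asarray(score_means)[score.astype(int) - 1]
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "item_id": item_id,
            "mean_pct_mvpa": y,
            "item_score": score,
            "age_years": age,
            "gender_code": gender,
            "season": "winter",
        }
    )


def test_noiseless_linear_data_recovers_coefficients_exactly():
    data = _make_dataset(np.random.default_rng(0))
    model = cal.fit_item_model(data, "act_evening", encoding="linear")
    assert model.coefficients["intercept"] == pytest.approx(10.0, abs=1e-8)
    assert model.coefficients["age_years"] == pytest.approx(1.2, abs=1e-8)
    assert model.coefficients["gender_code"] == pytest.approx(4.0, abs=1e-8)
    assert model.coefficients["item_score"] == pytest.approx(6.0, abs=1e-8)
    assert model.residual_sd == pytest.approx(0.0, abs=1e-6)
    assert model.r2 == pytest.approx(1.0)


def test_residuals_sum_to_zero_in_sample():
    """OLS with an intercept: fitted residuals average out to zero."""
    data = _make_dataset(np.random.default_rng(1), noise_sd=8.0)
    reg = cal.ItemCalibrationRegressor(encoding="linear")
    reg.fit(data, data["mean_pct_mvpa"])
    assert abs(reg.resid_.sum()) < 1e-8 * len(data)


def test_coefficient_bias_negligible_under_noise():
    """Monte Carlo: mean coefficient bias within 3 MC SEs of zero."""
    rng = np.random.default_rng(2)
    true = np.array([10.0, 1.2, 4.0, 6.0])
    names = ["intercept", "age_years", "gender_code", "item_score"]
    coefs = []
    for _ in range(40):
        data = _make_dataset(rng, n=300, noise_sd=8.0)
        m = cal.fit_item_model(data, "act_evening", encoding="linear")
        coefs.append([m.coefficients[k] for k in names])
    coefs = np.array(coefs)
    bias = coefs.mean(axis=0) - true
    se = coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs))
    assert (np.abs(bias) <= 3 * se).all()


def test_categorical_encoding_fits_plateau_better():
    """Data generated with a knot-4 plateau: the categorical fit's residual
    sum of squares is strictly below the linear fit's."""
    rng = np.random.default_rng(3)
    data = _make_dataset(rng, n=500, noise_sd=8.0,
                         score_means=(0.0, 8.0, 16.0, 24.0, 24.0))
    reg_lin = cal.ItemCalibrationRegressor(encoding="linear").fit(
        data, data["mean_pct_mvpa"]
    )
    reg_cat = cal.ItemCalibrationRegressor(encoding="categorical").fit(
        data, data["mean_pct_mvpa"]
    )
    assert reg_cat.rss_ < reg_lin.rss_
    assert cal.select_encoding(data, "act_evening") == "categorical"


def test_linear_generator_selects_linear_encoding():
    data = _make_dataset(np.random.default_rng(4), n=500, noise_sd=8.0)
    assert cal.select_encoding(data, "act_evening") == "linear"


def test_degenerate_designs_raise_or_fall_back():
    # constant item score: rank deficient under either encoding
    data = _make_dataset(np.random.default_rng(5), n=200, noise_sd=5.0)
    const = data.assign(item_score=3.0)
    with pytest.raises(cal.DegenerateDesignError):
        cal.fit_item_model(const, "act_evening", encoding="categorical")
    with pytest.raises(cal.DegenerateDesignError):
        cal.fit_item_model(const, "act_evening", encoding="linear")
    # categorical infeasible (observation floor) but linear fine: auto
    # falls back to linear with a warning
    small = _make_dataset(np.random.default_rng(5), n=45, noise_sd=5.0)
    with pytest.warns(UserWarning, match="falling back to linear"):
        model = cal.fit_item_model(small, "act_evening", encoding="auto")
    assert model.encoding == "linear"


def test_observation_floor_enforced():
    data = _make_dataset(np.random.default_rng(6), n=20)
    with pytest.raises(ValueError, match="floor"):
        cal.fit_item_model(data, "act_evening", encoding="linear", min_obs_per_coef=10)


def test_sklearn_param_interface():
    reg = cal.ItemCalibrationRegressor(encoding="linear", min_obs_per_coef=3)
    assert reg.get_params()["encoding"] == "linear"
    cloned = clone(reg)
    assert cloned.get_params() == reg.get_params()
    cloned.set_params(encoding="categorical")
    assert cloned.encoding == "categorical"
    data = _make_dataset(np.random.default_rng(7), n=60, noise_sd=2.0)
    reg.fit(data, data["mean_pct_mvpa"])
    pred = reg.predict(data)
    assert pred.shape == (60,)
    assert reg.score(data, data["mean_pct_mvpa"]) > 0.9  # RegressorMixin R^2


def test_model_serialization_round_trip():
    data = _make_dataset(np.random.default_rng(8), n=200, noise_sd=4.0)
    model = cal.fit_item_model(data, "act_evening", encoding="auto")
    back = cal.ItemCalibrationModel.from_dict(model.to_dict())
    np.testing.assert_allclose(back.predict(data), model.predict(data))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _flagged(rows):
    return scr.flag_valid_windows(pd.DataFrame(rows))


def _summary(pid, wt, d, pct, sched=240):
    start = pd.Timestamp(f"2015-03-{9 + (d - 1):02d} 18:00")
    worn = sched
    return {
        "participant_id": pid, "window_type": wt, "date": start.date(),
        "start": start, "end": start + pd.Timedelta(minutes=sched),
        "scheduled_minutes": sched, "worn_minutes": worn,
        "mvpa_minutes": int(round(pct / 100 * worn)),
        "imputed_minutes": 0, "imputed_mvpa_minutes": 0,
        "pct_mvpa": pct, "valid": pd.NA,
    }


def test_assemble_evening_only_participant_contributes_one_row(instrument):
    flagged = _flagged([
        _summary("A", "evening", d, 20.0) for d in range(1, 4)
    ])
    retention = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    demo = pd.DataFrame([
        {"participant_id": "A", "age_years": 12.0, "gender_code": 1, "season": "winter"}
    ])
    resp = pd.DataFrame([{"participant_id": "A", "act_evening": 4}])
    data, audit = cal.assemble_dataset(flagged, resp, demo, instrument, retention)
    assert len(data) == 1
    row = data.iloc[0]
    assert row["item_id"] == "act_evening"
    assert row["mean_pct_mvpa"] == pytest.approx(20.0)
    assert audit.empty


def test_assemble_occurrences_averaged_equally(instrument):
    flagged = _flagged([
        _summary("A", "evening", 1, 10.0),
        _summary("A", "evening", 2, 20.0),
        _summary("A", "evening", 3, 60.0),
    ])
    retention = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    demo = pd.DataFrame([{"participant_id": "A", "age_years": 12.0, "gender_code": 0}])
    resp = pd.DataFrame([{"participant_id": "A", "act_evening": 3}])
    data, _ = cal.assemble_dataset(flagged, resp, demo, instrument, retention)
    assert data["mean_pct_mvpa"].iloc[0] == pytest.approx(30.0)


def test_assemble_empty_retention_is_empty_not_error(instrument):
    flagged = _flagged([_summary("A", "evening", 1, 20.0, sched=240) | {"worn_minutes": 0, "mvpa_minutes": 0}])
    retention = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    data, _ = cal.assemble_dataset(
        flagged, pd.DataFrame({"participant_id": []}),
        pd.DataFrame({"participant_id": [], "age_years": [], "gender_code": []}),
        instrument, retention,
    )
    assert data.empty


def test_assemble_missing_demographics_audited(instrument):
    flagged = _flagged([_summary("A", "evening", d, 20.0) for d in range(1, 4)])
    retention = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    demo = pd.DataFrame([{"participant_id": "A", "age_years": np.nan, "gender_code": 1}])
    resp = pd.DataFrame([{"participant_id": "A", "act_evening": 4}])
    data, audit = cal.assemble_dataset(flagged, resp, demo, instrument, retention)
    assert data.empty
    assert audit["reason"].tolist() == ["missing age or gender"]


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def _intercept_model(item_id, intercept):
    return cal.ItemCalibrationModel(
        item_id=item_id, encoding="linear",
        coefficients={"intercept": intercept, "age_years": 0.0,
                      "gender_code": 0.0, "item_score": 0.0},
        score_levels=[1, 2, 3, 4, 5], residual_sd=0.0, n_used=50,
        r2=0.0, normality_p=1.0,
    )


@pytest.fixture()
def window_info(instrument):
    cfg = sim.paper_like_config(1, seed=0)
    cohort = sim.simulate_cohort(cfg)
    windows = seg.build_weekly_windows(cohort.schedule, cohort.week)
    return cal.window_frequencies(windows)


def test_intercept_only_models_predict_half_time(instrument, window_info):
    """All-zero slopes with intercept 50 predict 50% of every window's
    scheduled minutes; weekly = school + out-of-school."""
    models = {it.item_id: _intercept_model(it.item_id, 50.0)
              for it in instrument.activity_items}
    resp = pd.DataFrame([{"participant_id": "A", **{i.item_id: 3 for i in instrument.items}}])
    demo = pd.DataFrame([{"participant_id": "A", "age_years": 10, "gender_code": 0}])
    item_level, comps = cal.predict_composites(models, resp, demo, window_info, instrument)
    assert (item_level["predicted_pct_mvpa"] == 50.0).all()
    total = comps.iloc[0]
    assert total["weekly_min_week"] == pytest.approx(
        total["school_min_week"] + total["out_of_school_min_week"]
    )
    winfo = window_info.set_index("window_type")
    expected_minutes = 0.5 * sum(
        winfo.loc[it.window_type.value, "minutes_per_occurrence"]
        * winfo.loc[it.window_type.value, "per_week"]
        for it in instrument.activity_items
    )
    assert total["weekly_min_week"] == pytest.approx(expected_minutes)


def test_evening_window_arithmetic(instrument, window_info):
    """Evening at 10% of a 240-min window on 5 weekdays is 120 min/week."""
    models = {it.item_id: _intercept_model(it.item_id, 0.0)
              for it in instrument.activity_items}
    models["act_evening"] = _intercept_model("act_evening", 10.0)
    resp = pd.DataFrame([{"participant_id": "A", **{i.item_id: 3 for i in instrument.items}}])
    demo = pd.DataFrame([{"participant_id": "A", "age_years": 10, "gender_code": 0}])
    item_level, comps = cal.predict_composites(models, resp, demo, window_info, instrument)
    evening = item_level[item_level["item_id"] == "act_evening"].iloc[0]
    assert evening["predicted_min_week"] == pytest.approx(0.10 * 240 * 5)
    assert comps.iloc[0]["weekly_min_week"] == pytest.approx(120.0)


def test_negative_predictions_clipped_to_zero(instrument, window_info):
    models = {it.item_id: _intercept_model(it.item_id, -25.0)
              for it in instrument.activity_items}
    resp = pd.DataFrame([{"participant_id": "A", **{i.item_id: 1 for i in instrument.items}}])
    demo = pd.DataFrame([{"participant_id": "A", "age_years": 8, "gender_code": 0}])
    _, comps = cal.predict_composites(models, resp, demo, window_info, instrument)
    assert comps.iloc[0]["weekly_min_week"] == 0.0


def test_missing_response_uses_cohort_mean_and_is_flagged(instrument, window_info):
    models = {it.item_id: _intercept_model(it.item_id, 20.0)
              for it in instrument.activity_items}
    resp = pd.DataFrame([
        {"participant_id": "A", **{i: 4 for i in instrument.item_ids}},
        {"participant_id": "B", **{i: (np.nan if i == "act_evening" else 2)
                                   for i in instrument.item_ids}},
    ])
    demo = pd.DataFrame([
        {"participant_id": "A", "age_years": 10, "gender_code": 0},
        {"participant_id": "B", "age_years": 11, "gender_code": 1},
    ])
    item_level, comps = cal.predict_composites(models, resp, demo, window_info, instrument)
    b_evening = item_level[
        (item_level["participant_id"] == "B") & (item_level["item_id"] == "act_evening")
    ].iloc[0]
    assert bool(b_evening["score_imputed"])
    assert comps.set_index("participant_id").loc["B", "n_imputed_items"] == 1
    _, comps_skip = cal.predict_composites(
        models, resp, demo, window_info, instrument, missing_policy="skip"
    )
    assert (
        comps_skip.set_index("participant_id").loc["B", "weekly_min_week"]
        < comps.set_index("participant_id").loc["B", "weekly_min_week"]
    )


def test_cohort_level_recovery_via_truth_summaries(linear_cohort):
    """End to end on a noiseless linear-truth cohort: screening, assembly
    and per-item OLS recover the generating coefficients to 1e-8."""
    cohort = linear_cohort
    summaries = cohort.truth_window_summaries()
    retention = scr.retain_participants(summaries, scr.ScreeningRules(mode="item_wise"))
    data, _ = cal.assemble_dataset(
        summaries, cohort.responses, cohort.participants, cohort.instrument, retention
    )
    b0, b1, b2, b3 = sim.DEFAULT_LINEAR_COEFS
    for item in cohort.instrument.activity_items:
        model = cal.fit_item_model(data, item.item_id, encoding="linear",
                                   min_obs_per_coef=5)
        assert model.coefficients["intercept"] == pytest.approx(b0, abs=1e-8)
        assert model.coefficients["age_years"] == pytest.approx(b1, abs=1e-8)
        assert model.coefficients["gender_code"] == pytest.approx(b2, abs=1e-8)
        assert model.coefficients["item_score"] == pytest.approx(b3, abs=1e-8)


def test_item_wise_never_fits_on_fewer_rows_than_whole_week(screened_paper_cohort):
    cohort, _, flagged = screened_paper_cohort
    iw = scr.retain_participants(flagged, scr.ScreeningRules(mode="item_wise"))
    ww = scr.retain_participants(flagged, scr.ScreeningRules(mode="whole_week"))
    data_iw, _ = cal.assemble_dataset(
        flagged, cohort.responses, cohort.participants, cohort.instrument, iw
    )
    data_ww, _ = cal.assemble_dataset(
        flagged, cohort.responses, cohort.participants, cohort.instrument, ww
    )
    for item in cohort.instrument.activity_items:
        assert (
            (data_iw["item_id"] == item.item_id).sum()
            >= (data_ww["item_id"] == item.item_id).sum()
        )
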