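"""Per-item calibration of ordinal activity scores against measured %MVPA.

Each activity item is calibrated with its own ordinary least squares
regression

    pct_mvpa = b0 + b1 * age + b2 * gender + b3 * item_score + e,

where ``pct_mvpa`` is the participant's mean percent time in MVPA over
valid occurrences of the item's matched window, age is continuous years
and gender is coded 0 (female) / 1 (male).  Because some items relate
to monitor data nonlinearly -- a roughly linear rise through mid-scale
scores with a plateau at the top of the scale -- the item score term can
alternatively be entered categorically (one level effect per observed
score), and an information criterion chooses between the two encodings
per item.

Calibrated per-item predictions (percent of window time) are converted
to minutes by weighting each window's scheduled minutes by its weekly
frequency and summed into school / out-of-school / weekly composites.

The estimator follows scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) so it
composes with sklearn model-selection utilities; the module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .instrument import SECTION_SCHOOL, SECTION_OUT, InstrumentDefinition

logger = logging.getLogger(__name__)

COVARIATES = ("age_years", "gender_code")

DATASET_COLUMNS = [
    "participant_id", "item_id", "mean_pct_mvpa", "item_score",
    "age_years", "gender_code", "season",
]


class DegenerateDesignError(ValueError):
    """Raised when a calibration design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    summaries: pd.DataFrame,
    responses: pd.DataFrame,
    demographics: pd.DataFrame,
    instrument: InstrumentDefinition,
    retention: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-(participant, item) calibration table.

    For every retained (participant, window type) pair the participant's
    valid occurrences of that window are averaged with equal weight to a
    single ``mean_pct_mvpa``, joined with the participant's score on the
    linked item and demographics.  Retained participants lacking age,
    gender or the item response are excluded and audited.

    Returns ``(dataset, audit)``; the audit lists exclusions with reasons.
    """
    demo = demographics.set_index("participant_id")
    resp = responses.set_index("participant_id")
    valid = summaries[summaries["valid"].astype(bool) & summaries["pct_mvpa"].notna()]
    mean_pct = valid.groupby(["participant_id", "window_type"])["pct_mvpa"].mean()

    rows, audit_rows = [], []
    for item in instrument.activity_items:
        wt = item.window_type.value
        mask = (retention["window_type"] == wt) & retention["retained"]
        for pid in retention.loc[mask, "participant_id"]:
            if (pid, wt) not in mean_pct.index:
                audit_rows.append((pid, item.item_id, "no valid occurrence with data"))
                continue
            if pid not in demo.index or pd.isna(demo.loc[pid, "age_years"]) or pd.isna(
                demo.loc[pid, "gender_code"]
            ):
                audit_rows.append((pid, item.item_id, "missing age or gender"))
                continue
            score = resp.loc[pid, item.item_id] if (
                pid in resp.index and item.item_id in resp.columns
            ) else np.nan
            if pd.isna(score):
                audit_rows.append((pid, item.item_id, "missing item response"))
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "item_id": item.item_id,
                    "mean_pct_mvpa": float(mean_pct.loc[(pid, wt)]),
                    "item_score": float(score),
                    "age_years": float(demo.loc[pid, "age_years"]),
                    "gender_code": float(demo.loc[pid, "gender_code"]),
                    "season": demo.loc[pid, "season"] if "season" in demo.columns else pd.NA,
                }
            )
    dataset = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    audit = pd.DataFrame(audit_rows, columns=["participant_id", "item_id", "reason"])
    return dataset, audit


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class ItemCalibrationRegressor(RegressorMixin, BaseEstimator):
    """OLS calibration regression for one questionnaire item.

    Parameters
    ----------
    encoding : {"linear", "categorical", "auto"}
        How the ordinal item score enters the design.  ``linear`` uses a
        single slope; ``categorical`` one level effect per observed
        score (treatment-coded against the lowest observed level),
        which accommodates plateauing items.  ``auto`` fits both and
        keeps the encoding with the better (lower) ``criterion``.
    criterion : {"bic", "aicc", "aic"}
        Information criterion used under ``encoding="auto"``.  BIC is
        the default: its consistency keeps the simpler linear encoding
        under a truly linear item while still detecting clear plateaus.
    min_obs_per_coef : int
        Required observations per estimated coefficient.
    covariates : tuple of str
        Demographic columns entered alongside the item score.
    """

    def __init__(
        self,
        encoding: str = "auto",
        criterion: str = "bic",
        min_obs_per_coef: int = 10,
        covariates: tuple = COVARIATES,
    ):
        self.encoding = encoding
        self.criterion = criterion
        self.min_obs_per_coef = min_obs_per_coef
        self.covariates = covariates

    # -- design construction ------------------------------------------
    def _design(self, X: pd.DataFrame, encoding: str, levels=None):
        cols = {"intercept": np.ones(len(X))}
        for cov in self.covariates:
            cols[cov] = np.asarray(X[cov], dtype=float)
        score = np.asarray(X["item_score"], dtype=float)
        if encoding == "linear":
            cols["item_score"] = score
        else:
            if levels is None:
                levels = sorted(np.unique(score))
            else:
                # unseen levels map to the nearest level observed at fit time
                lev = np.asarray(levels, dtype=float)
                score = lev[np.abs(score[:, None] - lev[None, :]).argmin(axis=1)]
            for level in levels[1:]:
                cols[f"score[{level:g}]"] = (score == level).astype(float)
        return pd.DataFrame(cols, index=X.index), levels

    def _fit_one(self, X: pd.DataFrame, y, encoding: str):
        design, levels = self._design(X, encoding)
        if encoding == "categorical" and len(levels) < 2:
            raise DegenerateDesignError(
                "categorical encoding needs >= 2 observed score levels, got "
                f"{len(levels)}"
            )
        n, k = design.shape
        if n < self.min_obs_per_coef * k:
            raise ValueError(
                f"{n} observations below the floor of {self.min_obs_per_coef} "
                f"per coefficient ({k} coefficients)"
            )
        mat = design.to_numpy()
        if np.linalg.matrix_rank(mat) < k:
            raise DegenerateDesignError(
                f"rank-deficient design under {encoding} encoding "
                f"(columns: {list(design.columns)})"
            )
        res = sm.OLS(np.asarray(y, dtype=float), mat).fit()
        aicc = res.aic + (2 * k * (k + 1)) / max(n - k - 1, 1)
        crit = {"bic": res.bic, "aic": res.aic, "aicc": aicc}[self.criterion]
        return res, design.columns.tolist(), levels, crit

    def fit(self, X: pd.DataFrame, y):
        """Fit on a frame with columns ``item_score`` + covariates."""
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")

        if self.encoding in ("linear", "categorical"):
            chosen = self.encoding
            res, names, levels, crit = self._fit_one(X, y, chosen)
            self.criterion_values_ = {chosen: float(crit)}
        elif self.encoding == "auto":
            res_lin, names_lin, _, crit_lin = self._fit_one(X, y, "linear")
            try:
                res_cat, names_cat, levels, crit_cat = self._fit_one(
                    X, y, "categorical"
                )
            except (DegenerateDesignError, ValueError) as exc:
                warnings.warn(
                    f"categorical encoding unavailable ({exc}); "
                    "falling back to linear"
                )
                res_cat = None
            self.criterion_values_ = {"linear": float(crit_lin)}
            if res_cat is not None:
                self.criterion_values_["categorical"] = float(crit_cat)
            if res_cat is not None and crit_cat < crit_lin:
                chosen, res, names = "categorical", res_cat, names_cat
            else:
                chosen, res, names = "linear", res_lin, names_lin
                levels = None
        else:
            raise ValueError(f"unknown encoding {self.encoding!r}")

        if chosen == "linear":
            levels = sorted(np.unique(np.asarray(X["item_score"], dtype=float)))
        self.encoding_ = chosen
        self.coef_ = dict(zip(names, (float(v) for v in res.params)))
        self.score_levels_ = [float(v) for v in levels]
        self.n_used_ = int(res.nobs)
        self.resid_sd_ = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        self.r2_ = float(res.rsquared)
        self.rss_ = float(res.ssr)
        # residual-normality summary (Jarque-Bera p); NaN for tiny fits
        try:
            self.normality_p_ = float(sm.stats.jarque_bera(res.resid)[1])
        except Exception:  # pragma: no cover
            self.normality_p_ = float("nan")
        self.resid_ = np.asarray(res.resid)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "encoding_"):
            raise ValueError("estimator is not fitted")
        X = pd.DataFrame(X).reset_index(drop=True)
        design, _ = self._design(
            X,
            self.encoding_,
            levels=self.score_levels_ if self.encoding_ == "categorical" else None,
        )
        beta = np.array([self.coef_[c] for c in design.columns])
        return design.to_numpy() @ beta


# ---------------------------------------------------------------------------
# model records (serializable)
# ---------------------------------------------------------------------------

@dataclass
class ItemCalibrationModel:
    """Fitted coefficients and diagnostics for one item's regression."""

    item_id: str
    encoding: str
    coefficients: dict[str, float]
    score_levels: list[float]
    residual_sd: float
    n_used: int
    r2: float
    normality_p: float
    covariates: tuple = COVARIATES
    criterion_values: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_regressor(
        cls, item_id: str, reg: ItemCalibrationRegressor
    ) -> "ItemCalibrationModel":
        return cls(
            item_id=item_id,
            encoding=reg.encoding_,
            coefficients=dict(reg.coef_),
            score_levels=list(reg.score_levels_),
            residual_sd=reg.resid_sd_,
            n_used=reg.n_used_,
            r2=reg.r2_,
            normality_p=reg.normality_p_,
            covariates=tuple(reg.covariates),
            criterion_values=dict(getattr(reg, "criterion_values_", {})),
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        reg = ItemCalibrationRegressor(
            encoding=self.encoding, covariates=self.covariates
        )
        reg.encoding_ = self.encoding
        reg.coef_ = self.coefficients
        reg.score_levels_ = self.score_levels
        return reg.predict(X)

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "encoding": self.encoding,
            "coefficients": self.coefficients,
            "score_levels": self.score_levels,
            "residual_sd": self.residual_sd,
            "n_used": self.n_used,
            "r2": self.r2,
            "normality_p": self.normality_p,
            "covariates": list(self.covariates),
            "criterion_values": self.criterion_values,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemCalibrationModel":
        d = dict(d)
        d["covariates"] = tuple(d.get("covariates", COVARIATES))
        return cls(**d)


def fit_item_model(
    data: pd.DataFrame,
    item_id: str,
    encoding: str = "auto",
    min_obs_per_coef: int = 10,
    criterion: str = "bic",
) -> ItemCalibrationModel:
    """Fit one item's calibration regression from the assembled dataset."""
    rows = data[data["item_id"] == item_id]
    if rows.empty:
        raise ValueError(f"no calibration rows for item {item_id!r}")
    reg = ItemCalibrationRegressor(
        encoding=encoding, criterion=criterion, min_obs_per_coef=min_obs_per_coef
    )
    try:
        reg.fit(rows, rows["mean_pct_mvpa"])
    except (DegenerateDesignError, ValueError) as exc:
        raise type(exc)(f"item {item_id!r}: {exc}") from exc
    return ItemCalibrationModel.from_regressor(item_id, reg)


def select_encoding(
    data: pd.DataFrame,
    item_id: str,
    criterion: str = "bic",
    min_obs_per_coef: int = 10,
) -> str:
    """Choose ``linear`` or ``categorical`` for one item by the criterion."""
    model = fit_item_model(
        data, item_id, encoding="auto",
        min_obs_per_coef=min_obs_per_coef, criterion=criterion,
    )
    return model.encoding


def fit_all_items(
    data: pd.DataFrame,
    instrument: InstrumentDefinition,
    encoding: str = "auto",
    min_obs_per_coef: int = 10,
    criterion: str = "bic",
) -> dict[str, ItemCalibrationModel]:
    models = {}
    for item in instrument.activity_items:
        models[item.item_id] = fit_item_model(
            data, item.item_id, encoding=encoding,
            min_obs_per_coef=min_obs_per_coef, criterion=criterion,
        )
    return models


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def window_frequencies(windows: pd.DataFrame) -> pd.DataFrame:
    """Per window type: minutes per occurrence (mean) and occurrences/week."""
    g = windows.groupby("window_type")["scheduled_minutes"]
    return pd.DataFrame(
        {"minutes_per_occurrence": g.mean(), "per_week": g.size()}
    ).reset_index()


@dataclass
class CompositeEstimate:
    """Calibrated weekly MVPA minutes for one participant."""

    participant_id: str
    item_minutes: dict[str, float]
    item_pct: dict[str, float]
    school_min_week: float
    out_of_school_min_week: float
    weekly_min_week: float
    imputed_items: list[str] = field(default_factory=list)


def predict_composites(
    models: dict[str, ItemCalibrationModel],
    responses: pd.DataFrame,
    demographics: pd.DataFrame,
    window_info: pd.DataFrame,
    instrument: InstrumentDefinition,
    missing_policy: str = "cohort_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict per-item and composite weekly MVPA minutes per participant.

    Per item: predicted %MVPA (clipped to [0, 100]) times the window's
    scheduled minutes times its weekly frequency.  Composites sum the
    school and out-of-school sections; weekly = school + out-of-school.
    A missing item response contributes the prediction at the cohort
    mean score (flagged) under ``missing_policy="cohort_mean"``, or is
    skipped under ``"skip"``.

    Returns ``(item_level, composites)`` frames.
    """
    if missing_policy not in ("cohort_mean", "skip"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    winfo = window_info.set_index("window_type")
    demo = demographics.set_index("participant_id")
    resp = responses.set_index("participant_id")

    for item in instrument.activity_items:
        if item.item_id not in models:
            raise ValueError(f"no fitted model for activity item {item.item_id!r}")

    cohort_means = {
        item.item_id: float(resp[item.item_id].dropna().mean())
        if item.item_id in resp.columns and resp[item.item_id].notna().any()
        else (instrument.scale_min + instrument.scale_max) / 2
        for item in instrument.activity_items
    }

    item_rows, comp_rows = [], []
    for pid in resp.index:
        if pid not in demo.index:
            continue
        totals = {SECTION_SCHOOL: 0.0, SECTION_OUT: 0.0}
        imputed_items = []
        for item in instrument.activity_items:
            wt = item.window_type.value
            minutes = float(winfo.loc[wt, "minutes_per_occurrence"])
            per_week = float(winfo.loc[wt, "per_week"])
            score = resp.loc[pid, item.item_id] if item.item_id in resp.columns else np.nan
            flagged = False
            if pd.isna(score):
                if missing_policy == "skip":
                    continue
                score = cohort_means[item.item_id]
                flagged = True
                imputed_items.append(item.item_id)
            X = pd.DataFrame(
                {
                    "age_years": [float(demo.loc[pid, "age_years"])],
                    "gender_code": [float(demo.loc[pid, "gender_code"])],
                    "item_score": [float(score)],
                }
            )
            pct = float(np.clip(models[item.item_id].predict(X)[0], 0.0, 100.0))
            mins = pct / 100.0 * minutes * per_week
            totals[item.section] += mins
            item_rows.append(
                {
                    "participant_id": pid,
                    "item_id": item.item_id,
                    "window_type": wt,
                    "predicted_pct_mvpa": pct,
                    "predicted_min_week": mins,
                    "score_imputed": flagged,
                }
            )
        comp_rows.append(
            {
                "participant_id": pid,
                "school_min_week": totals[SECTION_SCHOOL],
                "out_of_school_min_week": totals[SECTION_OUT],
                "weekly_min_week": totals[SECTION_SCHOOL] + totals[SECTION_OUT],
                "n_imputed_items": len(imputed_items),
            }
        )
    item_level = pd.DataFrame(item_rows)
    composites = pd.DataFrame(comp_rows)
    return item_level, composites


def observed_weekly_minutes(
    summaries: pd.DataFrame,
    window_info: pd.DataFrame,
    instrument: InstrumentDefinition,
    require_all_windows: bool = True,
) -> pd.DataFrame:
    """Accelerometer-based weekly MVPA minutes per participant.

    Mirrors the composite weighting: for each activity window type, the
    mean %MVPA over the participant's valid occurrences times scheduled
    minutes times weekly frequency.  With ``require_all_windows`` only
    participants with >= 1 valid occurrence of every activity window
    type are returned (others' weekly totals would not be comparable).
    """
    winfo = window_info.set_index("window_type")
    wts = [it.window_type.value for it in instrument.activity_items]
    valid = summaries[summaries["valid"].astype(bool) & summaries["pct_mvpa"].notna()]
    mean_pct = (
        valid[valid["window_type"].isin(wts)]
        .groupby(["participant_id", "window_type"])["pct_mvpa"]
        .mean()
        .unstack()
    )
    if require_all_windows:
        mean_pct = mean_pct.dropna(subset=[w for w in wts if w in mean_pct.columns])
        mean_pct = mean_pct.reindex(columns=wts)
        mean_pct = mean_pct.dropna(axis=0)
    rows = []
    for pid, row in mean_pct.iterrows():
        total = 0.0
        for wt in wts:
            if wt not in row.index or pd.isna(row[wt]):
                continue
            total += (
                row[wt] / 100.0
                * float(winfo.loc[wt, "minutes_per_occurrence"])
                * float(winfo.loc[wt, "per_week"])
            )
        rows.append({"participant_id": pid, "observed_min_week": total})
    return pd.DataFrame(rows, columns=["participant_id", "observed_min_week"])
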