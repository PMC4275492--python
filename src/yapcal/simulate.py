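"""Synthetic cohorts with the statistical structure the calibration assumes.

The simulator emulates the four pipeline inputs -- minute-level monitor
streams, a weekly school schedule, questionnaire responses and
documented-nonwear activity logs -- for a cohort of youth spanning
elementary, middle and high school grades, both genders and multiple
seasons.  The latent model: each participant carries a true percent
time in MVPA per window type, drawn from a normal (truncated to
[0, 100]) whose mean shifts with age group, gender and season; daily
window occurrences vary around that latent value; self-reported item
scores are a discretized monotone transform of the latent value plus
rounded Gaussian reporting noise; monitor streams realize each window's
%MVPA minute-by-minute, plus measurement noise, masked by nonwear bouts
whose frequency increases with age group and of which only a
configurable fraction is documented in the log.

Two generating modes exist: ``window_normal`` (the realistic preset
above) and ``item_linear``, where the true %MVPA of each item's window
is an exact linear function of age, gender and the integer item score
-- the regime in which calibration regressions recover the generating
coefficients exactly when all noise is switched off.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import io as _io
from .instrument import InstrumentDefinition, default_instrument, SECTION_SEDENTARY
from .screen import DEFAULT_MET_TABLE
from .segment import AccelStream, ScheduleConfig, WindowType, build_weekly_windows, week_dates

# log activities the simulator draws for documented nonwear bouts
_LOG_ACTIVITIES = ("walking", "basketball", "soccer", "tv_watching", "reading", "video_games")
_LOG_WEIGHTS = (0.2, 0.15, 0.15, 0.2, 0.15, 0.15)

AGE_RANGES = {"elementary": (8.0, 11.0), "middle": (11.0, 14.0), "high": (14.0, 18.0)}


# ---------------------------------------------------------------------------
# item links: monotone map between ordinal score and window %MVPA
# ---------------------------------------------------------------------------

class ItemLink:
    """Monotone relation between an item's score and its window %MVPA.

    ``expected_pct(score)`` maps score -> expected %MVPA (used to define
    the generator); ``expected_score(pct, rng)`` is the pseudo-inverse
    used when simulating a response from a participant's latent truth.
    """

    scale_min: int = 1
    scale_max: int = 5

    def expected_pct(self, score):  # pragma: no cover - abstract
        raise NotImplementedError

    def expected_score(self, pct, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def check_monotone(self) -> None:
        grid = [self.expected_pct(s) for s in range(self.scale_min, self.scale_max + 1)]
        if any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("item link must be non-decreasing in the score")


@dataclass
class LinearLink(ItemLink):
    """Expected %MVPA rises linearly over the whole score range."""

    base: float = 0.0           # expected pct at the scale minimum
    slope: float = 8.0          # pct MVPA per score unit
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be non-negative")

    def expected_pct(self, score):
        return self.base + self.slope * (np.asarray(score, dtype=float) - self.scale_min)

    def expected_score(self, pct, rng=None):
        if self.slope == 0:
            return np.full_like(np.asarray(pct, dtype=float), (self.scale_min + self.scale_max) / 2)
        raw = (np.asarray(pct, dtype=float) - self.base) / self.slope + self.scale_min
        return np.clip(raw, self.scale_min, self.scale_max)


@dataclass
class PlateauLink(ItemLink):
    """Linear below the knot score, flat at and above it.

    Mirrors items whose observed %MVPA rises through mid-scale scores
    and plateaus at the top of the scale.
    """

    knot: int = 4
    slope: float = 8.0
    base: float = 0.0
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if not self.scale_min <= self.knot <= self.scale_max:
            raise ValueError("knot must lie within the scale bounds")

    def expected_pct(self, score):
        s = np.minimum(np.asarray(score, dtype=float), self.knot)
        return self.base + self.slope * (s - self.scale_min)

    @property
    def plateau_pct(self) -> float:
        return float(self.base + self.slope * (self.knot - self.scale_min))

    def expected_score(self, pct, rng=None):
        scalar = np.ndim(pct) == 0
        pct = np.atleast_1d(np.asarray(pct, dtype=float))
        if self.slope == 0:
            out = np.full_like(pct, (self.scale_min + self.scale_max) / 2)
            return out[0] if scalar else out
        raw = np.clip(
            (pct - self.base) / self.slope + self.scale_min,
            self.scale_min, self.scale_max,
        )
        at_top = pct >= self.plateau_pct
        if at_top.any():
            # on the plateau the score is uninformative within [knot, max]
            if rng is None:
                spread = np.full(at_top.sum(), (self.knot + self.scale_max) / 2)
            else:
                spread = rng.uniform(self.knot, self.scale_max, size=int(at_top.sum()))
            raw = raw.copy()
            raw[at_top] = spread
        return raw[0] if scalar else raw


def make_plateau_link(
    knot_score: int, slope: float, base: float = 0.0,
    scale_min: int = 1, scale_max: int = 5,
) -> PlateauLink:
    """Item link that is linear below ``knot_score`` and flat above it."""
    link = PlateauLink(
        knot=knot_score, slope=slope, base=base,
        scale_min=scale_min, scale_max=scale_max,
    )
    link.check_monotone()
    return link


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_WINDOW_MEAN = {
    WindowType.BEFORE_SCHOOL: 15.0,
    WindowType.TRANSPORT_TO_SCHOOL: 30.0,
    WindowType.RECESS: 38.0,
    WindowType.PHYSICAL_EDUCATION: 45.0,
    WindowType.LUNCH: 18.0,
    WindowType.TRANSPORT_FROM_SCHOOL: 30.0,
    WindowType.AFTER_SCHOOL: 22.0,
    WindowType.EVENING: 14.0,
    WindowType.SATURDAY: 12.0,
    WindowType.SUNDAY: 10.0,
}
_DEFAULT_WINDOW_SD = {wt: 8.0 for wt in WindowType}


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic cohort.

    Defaults describe a realistic school cohort: equal elementary /
    middle / high mix, balanced genders, two seasons, moderate window
    %MVPA levels that decline with age, reporting noise of ~0.6 score
    units, minute-level measurement noise of 3 %MVPA, and a nonwear
    process whose bout rate rises with age group (overall wear around
    70-85% of the waking day, falling with age) with 60% of bouts
    documented in the activity log.
    """

    n_participants: int = 200
    age_group_mix: dict = field(
        default_factory=lambda: {"elementary": 1 / 3, "middle": 1 / 3, "high": 1 / 3}
    )
    gender_mix: float = 0.5  # fraction male
    seasons: tuple = ("winter", "spring")
    season_shift: dict = field(
        default_factory=lambda: {"winter": -2.0, "spring": 2.0}
    )
    window_mvpa_mean: dict = field(default_factory=lambda: dict(_DEFAULT_WINDOW_MEAN))
    window_mvpa_sd: dict = field(default_factory=lambda: dict(_DEFAULT_WINDOW_SD))
    age_group_shift: dict = field(
        default_factory=lambda: {"elementary": 4.0, "middle": 0.0, "high": -4.0}
    )
    gender_shift: float = 3.0  # male minus female, pct MVPA
    day_sd: float = 6.0  # day-to-day SD of a window's true %MVPA
    mvpa_measurement_noise_sd: float = 3.0  # monitor noise on window %MVPA
    reporting_noise_sd: float = 0.6  # score units before rounding
    nonwear_rate_per_day: dict = field(
        default_factory=lambda: {"elementary": 1.5, "middle": 2.5, "high": 3.5}
    )
    nonwear_mean_minutes: float = 90.0
    nonwear_documented_fraction: float = 0.6
    item_links: dict | None = None  # item_id -> ItemLink; None = preset links
    truth_model: str = "window_normal"  # or "item_linear"
    item_linear_coefs: dict | None = None  # item_id -> (b0, b1_age, b2_gender, b3_score)
    deterministic_minutes: bool = False  # realize window %MVPA without Bernoulli noise
    background_mvpa_prob: float = 0.05  # outside scheduled windows
    week_start: date = date(2015, 3, 9)  # a Monday
    school_start: str = "08:15"
    school_end: str = "15:30"
    recess_time: tuple = ("10:00", "10:20")
    lunch_time: tuple = ("12:00", "12:40")
    pe_time: tuple = ("13:30", "14:15")
    pe_weekdays: tuple = (0, 2, 4)  # Mon/Wed/Fri
    mvpa_met_threshold: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if abs(sum(self.age_group_mix.values()) - 1.0) > 1e-9:
            raise ValueError("age_group_mix proportions must sum to 1")
        if not 0 <= self.gender_mix <= 1:
            raise ValueError("gender_mix must lie in [0, 1]")
        for name in ("day_sd", "mvpa_measurement_noise_sd", "reporting_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for sd in self.window_mvpa_sd.values():
            if sd < 0:
                raise ValueError("window_mvpa_sd values must be >= 0")
        if self.truth_model not in ("window_normal", "item_linear"):
            raise ValueError(f"unknown truth_model {self.truth_model!r}")
        if isinstance(self.week_start, str):
            self.week_start = date.fromisoformat(self.week_start)
        self.window_mvpa_mean = {
            WindowType(k): float(v) for k, v in self.window_mvpa_mean.items()
        }
        self.window_mvpa_sd = {
            WindowType(k): float(v) for k, v in self.window_mvpa_sd.items()
        }
        if self.item_links is not None:
            for link in self.item_links.values():
                link.check_monotone()

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d.pop("item_links", None)
        return d


def paper_like_config(n_participants: int = 200, seed: int = 0, **overrides) -> SimulationConfig:
    """The default realistic preset (age-graded nonwear, plateau on PE)."""
    return SimulationConfig(n_participants=n_participants, rng_seed=seed, **overrides)


def noiseless_config(n_participants: int = 100, seed: int = 0, **overrides) -> SimulationConfig:
    """All noise off, no nonwear, deterministic minute patterns."""
    kwargs = dict(
        n_participants=n_participants,
        rng_seed=seed,
        day_sd=0.0,
        mvpa_measurement_noise_sd=0.0,
        reporting_noise_sd=0.0,
        nonwear_rate_per_day={"elementary": 0.0, "middle": 0.0, "high": 0.0},
        deterministic_minutes=True,
        background_mvpa_prob=0.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def linear_truth_config(
    n_participants: int = 150, seed: int = 0, noiseless: bool = True, **overrides
) -> SimulationConfig:
    """Truth exactly linear in (age, gender, item score) per item."""
    maker = noiseless_config if noiseless else paper_like_config
    return maker(
        n_participants=n_participants, seed=seed,
        truth_model="item_linear", **overrides,
    )


DEFAULT_LINEAR_COEFS = (10.0, 1.2, 4.0, 6.0)  # intercept, age, gender, score


def default_item_links(
    instrument: InstrumentDefinition, config: SimulationConfig
) -> dict[str, ItemLink]:
    """Preset links: linear everywhere, plateau (knot 4) for the PE item."""
    links: dict[str, ItemLink] = {}
    for item in instrument.activity_items:
        mean = config.window_mvpa_mean[item.window_type]
        slope = 8.0
        base = mean - 2.0 * slope  # score 3 maps to the window mean
        if item.window_type is WindowType.PHYSICAL_EDUCATION:
            links[item.item_id] = make_plateau_link(
                4, slope, base=base,
                scale_min=instrument.scale_min, scale_max=instrument.scale_max,
            )
        else:
            links[item.item_id] = LinearLink(
                base=base, slope=slope,
                scale_min=instrument.scale_min, scale_max=instrument.scale_max,
            )
    return links


# ---------------------------------------------------------------------------
# the cohort container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Latent truth plus the four observable inputs for one simulated study."""

    config: SimulationConfig
    instrument: InstrumentDefinition
    participants: pd.DataFrame
    schedule: ScheduleConfig
    week: list
    truth: pd.DataFrame  # participant_id, window_type, date, true_pct
    streams: dict[str, AccelStream]
    responses: pd.DataFrame  # wide: participant_id + item columns
    logs: pd.DataFrame
    met_table: dict[str, float]

    def truth_window_summaries(self) -> pd.DataFrame:
        """Window summaries taken from the latent truth (no monitor).

        Every scheduled occurrence appears, fully 'worn', with
        ``pct_mvpa`` equal to the generating truth and ``valid`` True.
        Useful for noise-free parameter-recovery analyses.
        """
        windows = build_weekly_windows(self.schedule, self.week)
        truth = self.truth.copy()
        merged = truth.merge(windows, on=["window_type", "date"], how="left")
        merged["worn_minutes"] = merged["scheduled_minutes"]
        merged["mvpa_minutes"] = (
            merged["true_pct"] / 100.0 * merged["scheduled_minutes"]
        )
        merged["imputed_minutes"] = 0
        merged["imputed_mvpa_minutes"] = 0
        merged["pct_mvpa"] = merged["true_pct"]
        merged["valid"] = True
        cols = [
            "participant_id", "window_type", "date", "start", "end",
            "scheduled_minutes", "worn_minutes", "mvpa_minutes",
            "imputed_minutes", "imputed_mvpa_minutes", "pct_mvpa", "valid",
        ]
        return merged[cols]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig, instrument: InstrumentDefinition | None = None
) -> SyntheticCohort:
    """Generate a cohort; deterministic given ``config.rng_seed``.

    A participant's entire record derives from a per-participant child
    seed spawned from the shared seed, so enlarging ``n_participants``
    leaves earlier participants' data unchanged.
    """
    instrument = instrument or default_instrument()
    links = config.item_links or default_item_links(instrument, config)
    schedule = ScheduleConfig(
        school_start=config.school_start,
        school_end=config.school_end,
        special_windows=_build_special_windows(config),
    )
    week = week_dates(config.week_start)
    windows = build_weekly_windows(schedule, week)
    root_ss = np.random.SeedSequence(config.rng_seed)
    cohort_rng = np.random.default_rng(root_ss.spawn(1)[0])

    groups = list(config.age_group_mix)
    probs = np.array([config.age_group_mix[g] for g in groups])

    part_rows, truth_rows, resp_rows, log_rows = [], [], [], []
    streams: dict[str, AccelStream] = {}
    for i in range(config.n_participants):
        pid = f"P{i + 1:04d}"
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(1, i))
        )
        group = groups[rng.choice(len(groups), p=probs)]
        lo, hi = AGE_RANGES[group]
        age = round(float(rng.uniform(lo, hi)), 1)
        male = int(rng.random() < config.gender_mix)
        season = config.seasons[int(rng.integers(len(config.seasons)))]
        part_rows.append(
            {
                "participant_id": pid,
                "age_years": age,
                "age_group": group,
                "gender": "M" if male else "F",
                "gender_code": male,
                "season": season,
            }
        )
        latent, scores = _participant_latent(
            config, instrument, links, rng, group, age, male, season
        )
        resp_rows.append({"participant_id": pid, **scores})
        truth_by_wt_date = _daily_truth(config, windows, latent, rng)
        for (wt, d), val in truth_by_wt_date.items():
            truth_rows.append(
                {"participant_id": pid, "window_type": wt, "date": d, "true_pct": val}
            )
        stream, logs = _participant_stream(
            config, windows, truth_by_wt_date, rng, pid, group
        )
        streams[pid] = stream
        log_rows.extend(logs)

    participants = pd.DataFrame(part_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "window_type", "date", "true_pct"]
    )
    responses = pd.DataFrame(resp_rows)
    logs = pd.DataFrame(
        log_rows, columns=["participant_id", "date", "start", "end", "activity"]
    )
    return SyntheticCohort(
        config=config,
        instrument=instrument,
        participants=participants,
        schedule=schedule,
        week=week,
        truth=truth,
        streams=streams,
        responses=responses,
        logs=logs,
        met_table=dict(DEFAULT_MET_TABLE),
    )


def _build_special_windows(config: SimulationConfig) -> dict:
    special: dict = {}
    for offset in range(5):  # weekdays
        d = config.week_start + timedelta(days=offset)
        wins = {
            WindowType.RECESS: config.recess_time,
            WindowType.LUNCH: config.lunch_time,
        }
        if offset in config.pe_weekdays:
            wins[WindowType.PHYSICAL_EDUCATION] = config.pe_time
        special[d] = wins
    return special


def _participant_latent(config, instrument, links, rng, group, age, male, season):
    """Latent per-window-type %MVPA and the participant's item scores."""
    latent: dict[WindowType, float] = {}
    scores: dict[str, int] = {}
    smin, smax = instrument.scale_min, instrument.scale_max
    if config.truth_model == "item_linear":
        coefs = config.item_linear_coefs or {}
        for item in instrument.activity_items:
            b0, b1, b2, b3 = coefs.get(item.item_id, DEFAULT_LINEAR_COEFS)
            score = int(rng.integers(smin, smax + 1))
            scores[item.item_id] = score
            latent[item.window_type] = float(
                np.clip(b0 + b1 * age + b2 * male + b3 * score, 0.0, 100.0)
            )
    else:
        shift = (
            config.age_group_shift[group]
            + config.gender_shift * male
            + config.season_shift.get(season, 0.0)
        )
        for wt in WindowType:
            mu = config.window_mvpa_mean[wt] + shift
            sd = config.window_mvpa_sd[wt]
            val = _trunc_normal(rng, mu, sd, 0.0, 100.0)
            latent[wt] = float(val)
        for item in instrument.activity_items:
            link = links[item.item_id]
            cont = float(link.expected_score(latent[item.window_type], rng))
            if config.reporting_noise_sd > 0:
                cont += rng.normal(0.0, config.reporting_noise_sd)
            scores[item.item_id] = int(np.clip(round(cont), smin, smax))
    # sedentary items: inverse of overall activity plus reporting noise
    if scores:
        act_mean = float(np.mean(list(scores.values())))
    else:  # pragma: no cover
        act_mean = (smin + smax) / 2
    for item in instrument.items_in_section(SECTION_SEDENTARY):
        cont = (smin + smax) - act_mean
        if config.reporting_noise_sd > 0:
            cont += rng.normal(0.0, max(config.reporting_noise_sd, 0.3))
        scores[item.item_id] = int(np.clip(round(cont), smin, smax))
    return latent, scores


def _trunc_normal(rng, mu, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mu, lo, hi))
    for _ in range(100):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mu, lo, hi))  # pragma: no cover - extreme configs


def _daily_truth(config, windows, latent, rng):
    """True %MVPA per (window_type, date) occurrence for one participant."""
    out = {}
    for win in windows.itertuples():
        wt = WindowType(win.window_type)
        base = latent[wt]
        if config.day_sd > 0:
            val = float(np.clip(base + rng.normal(0.0, config.day_sd), 0.0, 100.0))
        else:
            val = base
        out[(win.window_type, win.date)] = val
    return out


def _participant_stream(config, windows, truth_by_wt_date, rng, pid, group):
    """Minute records for the full week plus documented-nonwear log rows."""
    wins_by_date: dict = {}
    for win in windows.itertuples():
        wins_by_date.setdefault(win.date, []).append(win)

    day_frames = []
    log_rows = []
    for d, day_windows in sorted(wins_by_date.items()):
        day_start = min(w.start for w in day_windows) - pd.Timedelta(minutes=15)
        day_end = max(w.end for w in day_windows)
        n_min = int((day_end - day_start).total_seconds() // 60)
        ts = pd.date_range(day_start, periods=n_min, freq="min")
        mvpa = np.zeros(n_min, dtype=np.int8)
        if not config.deterministic_minutes and config.background_mvpa_prob > 0:
            mvpa[:] = rng.random(n_min) < config.background_mvpa_prob
        for win in day_windows:
            i0 = int((win.start - day_start).total_seconds() // 60)
            i1 = int((win.end - day_start).total_seconds() // 60)
            p = truth_by_wt_date[(win.window_type, win.date)]
            if config.mvpa_measurement_noise_sd > 0:
                p = float(
                    np.clip(p + rng.normal(0.0, config.mvpa_measurement_noise_sd), 0, 100)
                )
            if config.deterministic_minutes:
                k = int(round(p / 100.0 * (i1 - i0)))
                mvpa[i0:i1] = 0
                mvpa[i0 : i0 + k] = 1
            else:
                mvpa[i0:i1] = rng.random(i1 - i0) < p / 100.0
        if config.deterministic_minutes:
            ee = np.where(mvpa == 1, 4.0, 1.5)
        else:
            ee = np.where(
                mvpa == 1,
                np.minimum(3.0 + rng.exponential(1.5, n_min), 12.0),
                rng.uniform(1.0, 2.9, n_min),
            )
        wear = np.ones(n_min, dtype=np.int8)

        # nonwear bouts: rate rises with age group; some are documented
        rate = config.nonwear_rate_per_day.get(group, 0.0)
        n_bouts = rng.poisson(rate) if rate > 0 else 0
        for _ in range(n_bouts):
            dur = int(max(10, round(rng.gamma(2.0, config.nonwear_mean_minutes / 2.0))))
            dur = min(dur, n_min - 1)
            start_idx = int(rng.integers(0, n_min - dur))
            wear[start_idx : start_idx + dur] = 0
            if rng.random() < config.nonwear_documented_fraction:
                activity = rng.choice(_LOG_ACTIVITIES, p=_LOG_WEIGHTS)
                log_rows.append(
                    {
                        "participant_id": pid,
                        "date": d,
                        "start": ts[start_idx],
                        "end": ts[start_idx] + pd.Timedelta(minutes=dur),
                        "activity": str(activity),
                    }
                )
        ee = np.where(wear == 1, ee, 0.0)
        mvpa = np.where(wear == 1, mvpa, 0).astype(np.int8)
        day_frames.append(
            pd.DataFrame(
                {"timestamp": ts, "ee_mets": np.round(ee, 2), "wear": wear, "mvpa": mvpa}
            )
        )
    records = pd.concat(day_frames, ignore_index=True)
    return AccelStream(participant_id=pid, records=records), log_rows


# ---------------------------------------------------------------------------
# writing the four input files
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Emit the pipeline's input files; round-trips through ``read_cohort``.

    Layout: ``participants.csv``, ``responses.csv``, ``logs.csv``,
    ``met_table.csv``, ``schedule.yml`` and ``streams/<pid>.csv``.
    Returns the mapping of artifact name to path.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = _io.file_metadata(
        seed=cohort.config.rng_seed,
        cfg_hash=_io.config_hash(cohort.config.to_jsonable()),
    )
    paths = {
        "participants": out_dir / "participants.csv",
        "responses": out_dir / "responses.csv",
        "logs": out_dir / "logs.csv",
        "met_table": out_dir / "met_table.csv",
        "schedule": out_dir / "schedule.yml",
        "streams": out_dir / "streams",
    }
    _io.write_participants(cohort.participants, paths["participants"], meta)
    _io.write_responses(cohort.responses, paths["responses"], meta)
    _io.write_logs(cohort.logs, paths["logs"], meta)
    _io.write_met_table(cohort.met_table, paths["met_table"], meta)
    _io.write_schedule(cohort.schedule, cohort.week[0], paths["schedule"], meta)
    paths["streams"].mkdir(exist_ok=True)
    for pid in sorted(cohort.streams):
        _io.write_stream(cohort.streams[pid], paths["streams"] / f"{pid}.csv", meta)
    return paths


def read_cohort(in_dir, instrument: InstrumentDefinition | None = None):
    """Read back the observables written by :func:`write_cohort`.

    Returns a :class:`SyntheticCohort` whose ``truth`` table is empty
    (the latent state is not part of the observable file set).
    """
    from pathlib import Path

    in_dir = Path(in_dir)
    participants = _io.read_participants(in_dir / "participants.csv")
    responses = _io.read_responses(in_dir / "responses.csv")
    logs = _io.read_logs(in_dir / "logs.csv")
    met_table = _io.read_met_table(in_dir / "met_table.csv")
    schedule, week_start = _io.read_schedule(in_dir / "schedule.yml")
    streams = {
        p.stem: _io.read_stream(p) for p in sorted((in_dir / "streams").glob("*.csv"))
    }
    return SyntheticCohort(
        config=SimulationConfig(n_participants=max(len(participants), 1)),
        instrument=instrument or default_instrument(),
        participants=participants,
        schedule=schedule,
        week=week_dates(date.fromisoformat(week_start)),
        truth=pd.DataFrame(
            columns=["participant_id", "window_type", "date", "true_pct"]
        ),
        streams=streams,
        responses=responses,
        logs=logs,
        met_table=met_table,
    )
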