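"""Readers and writers for the pipeline's delimited-text formats.

All tabular files are comma-delimited UTF-8 with a single header row,
preceded by ``#``-prefixed metadata lines (tool version, config hash,
seed) so any output can be reproduced exactly.  Timestamps are ISO-8601
local clock times; school scheduling is inherently local so no timezone
arithmetic is done anywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibrate import ItemCalibrationModel
from .segment import AccelStream, ScheduleConfig

TIMESTAMP_FMT = "%Y-%m-%d %H:%M"


class IOFormatError(ValueError):
    """Raised for files that do not match the expected format."""


def config_hash(config) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_metadata(seed=None, cfg_hash: str | None = None, **extra) -> dict:
    meta = {"tool": "yapcal", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if cfg_hash is not None:
        meta["config_hash"] = cfg_hash
    meta.update(extra)
    return meta


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path, required_columns=None, numeric_columns=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise IOFormatError(f"{path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise IOFormatError(f"{path}: missing required columns {missing}")
    for col in numeric_columns or ():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1  # 1-based data row
            raise IOFormatError(
                f"{path}: malformed value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced
    return df


def read_metadata(path) -> dict:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------

def write_stream(stream: AccelStream, path, meta: dict | None = None) -> None:
    rec = stream.records.copy()
    rec["timestamp"] = rec["timestamp"].dt.strftime(TIMESTAMP_FMT)
    write_table(rec[["timestamp", "ee_mets", "wear", "mvpa"]], path, meta)


def read_stream(path, participant_id: str | None = None) -> AccelStream:
    df = read_table(
        path,
        required_columns=["timestamp", "ee_mets", "wear"],
        numeric_columns=["ee_mets", "wear"],
    )
    if participant_id is None:
        participant_id = Path(path).stem
    return AccelStream.from_frame(participant_id, df)


# ---------------------------------------------------------------------------
# responses / participants / logs / MET table
# ---------------------------------------------------------------------------

def write_responses(responses: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(responses, path, meta)


def read_responses(path) -> pd.DataFrame:
    return read_table(path, required_columns=["participant_id"])


def write_participants(participants: pd.DataFrame, path, meta=None) -> None:
    write_table(participants, path, meta)


def read_participants(path) -> pd.DataFrame:
    return read_table(
        path,
        required_columns=["participant_id", "age_years", "gender_code"],
        numeric_columns=["age_years", "gender_code"],
    )


def write_logs(logs: pd.DataFrame, path, meta=None) -> None:
    out = logs.copy()
    for col in ("start", "end"):
        if col in out.columns and len(out):
            out[col] = pd.to_datetime(out[col]).dt.strftime(TIMESTAMP_FMT)
    write_table(out, path, meta)


def read_logs(path) -> pd.DataFrame:
    df = read_table(
        path, required_columns=["participant_id", "date", "start", "end", "activity"]
    )
    if len(df):
        df["start"] = pd.to_datetime(df["start"])
        df["end"] = pd.to_datetime(df["end"])
    return df


def write_met_table(met_table: dict[str, float], path, meta=None) -> None:
    df = pd.DataFrame(
        sorted(met_table.items()), columns=["activity", "met_value"]
    )
    write_table(df, path, meta)


def read_met_table(path) -> dict[str, float]:
    df = read_table(
        path, required_columns=["activity", "met_value"],
        numeric_columns=["met_value"],
    )
    return dict(zip(df["activity"], df["met_value"].astype(float)))


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def write_schedule(
    schedule: ScheduleConfig, week_start, path, meta: dict | None = None
) -> None:
    doc = {
        "_meta": {k: str(v) for k, v in (meta or {}).items()},
        "week_start": str(week_start),
        "school_start": schedule.school_start.strftime("%H:%M"),
        "school_end": schedule.school_end.strftime("%H:%M"),
        "special_windows": {
            str(d): {
                wt.value: [s.strftime("%H:%M"), e.strftime("%H:%M")]
                for wt, (s, e) in sorted(wins.items(), key=lambda kv: kv[0].value)
            }
            for d, wins in sorted(schedule.special_windows.items())
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_schedule(path) -> tuple[ScheduleConfig, str]:
    """Returns ``(schedule, week_start_iso)``."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise IOFormatError(f"{path}: malformed schedule file: {exc}") from exc
    if not isinstance(doc, dict) or "school_start" not in doc:
        raise IOFormatError(f"{path}: schedule file lacks school_start")
    schedule = ScheduleConfig(
        school_start=doc["school_start"],
        school_end=doc["school_end"],
        special_windows={
            d: {wt: tuple(times) for wt, times in wins.items()}
            for d, wins in (doc.get("special_windows") or {}).items()
        },
    )
    return schedule, str(doc.get("week_start", ""))


# ---------------------------------------------------------------------------
# models and reports
# ---------------------------------------------------------------------------

def write_models(
    models: dict[str, ItemCalibrationModel], path, meta: dict | None = None
) -> None:
    doc = {
        "_meta": meta or {},
        "models": [models[k].to_dict() for k in sorted(models)],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_models(path) -> dict[str, ItemCalibrationModel]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return {
        rec["item_id"]: ItemCalibrationModel.from_dict(rec)
        for rec in doc["models"]
    }


def write_json_report(obj: dict, path, meta: dict | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"_meta": meta or {}, **obj}, fh, indent=2, sort_keys=True)
        fh.write("\n")
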