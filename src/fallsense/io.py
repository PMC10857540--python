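"""On-disk formats: trial CSV, annotation/manifest JSON, feature table CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .features import CATALOGUE
from .recording import (
    CHANNELS,
    GroundTruthAnnotation,
    SENSORS,
    SensorBlock,
    TrialRecording,
)

TRIAL_COLUMNS = ("time_s", "sensor", "channel", "axis", "value")


class SchemaError(ValueError):
    pass


def trial_filename(trial: TrialRecording) -> str:
    return f"{trial.subject_id}_{trial.task_id}.csv"


def write_trial(trial: TrialRecording, path) -> None:
    """Long-format CSV: one row per (time, sensor, channel, axis) sample."""
    frames = []
    t = trial.time_s
    for sensor, blk in trial.sensors.items():
        for channel in CHANNELS:
            arr = getattr(blk, channel)
            for axis in range(3):
                frames.append(pd.DataFrame({
                    "time_s": t, "sensor": sensor, "channel": channel,
                    "axis": axis + 1, "value": arr[:, axis],
                }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trial(path, subject_id: str, task_id: str, fs_hz: float
               ) -> TrialRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"trial file missing columns: {sorted(missing)}")
    unknown = set(df["sensor"].unique()) - set(SENSORS)
    if unknown:
        raise SchemaError(f"unknown sensor labels: {sorted(unknown)}")
    sensors = {}
    for sensor, group in df.groupby("sensor", sort=False):
        chans = {}
        for channel, cgroup in group.groupby("channel", sort=False):
            if channel not in CHANNELS:
                raise SchemaError(f"unknown channel {channel!r}")
            axes = []
            for axis in (1, 2, 3):
                sub = cgroup[cgroup["axis"] == axis].sort_values("time_s")
                axes.append(sub["value"].to_numpy(dtype=float))
            if len({a.shape[0] for a in axes}) != 1:
                raise SchemaError(f"{sensor}/{channel}: axis lengths differ")
            chans[channel] = np.column_stack(axes)
        if set(chans) != set(CHANNELS):
            raise SchemaError(f"{sensor}: missing channels {set(CHANNELS) - set(chans)}")
        sensors[sensor] = SensorBlock(**chans)
    return TrialRecording(subject_id=subject_id, task_id=task_id, fs_hz=fs_hz,
                          sensors=sensors)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_annotation(ann: GroundTruthAnnotation, path) -> None:
    payload = {
        "subject_id": ann.subject_id,
        "task_id": ann.task_id,
        "events": _jsonable(ann.events),
        "params": _jsonable(ann.params),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotation(path) -> GroundTruthAnnotation:
    payload = json.loads(Path(path).read_text())
    return GroundTruthAnnotation(
        subject_id=payload["subject_id"], task_id=payload["task_id"],
        events=payload.get("events", {}), params=payload.get("params", {}),
    )


def write_manifest(path, profiles, trial_files: Sequence[str],
                   extra: Dict[str, object] | None = None) -> None:
    payload = {
        "subjects": [
            {"subject_id": p.subject_id, "group": p.group,
             "latent_mobility": p.latent_mobility}
            for p in profiles
        ],
        "trials": list(trial_files),
    }
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=1))


def write_feature_table(table: pd.DataFrame, path, schema_path=None) -> None:
    table.to_csv(path, float_format="%.17g")
    if schema_path is not None:
        schema = {
            "columns": [
                {
                    "name": e.name,
                    "task": e.task or "clinical",
                    "dual": e.dual,
                    "required_sensors": [sorted(req) for req in e.requires],
                }
                for e in CATALOGUE
            ],
            "label": {"name": "label", "encoding": {"faller": 1, "nonfaller": 0}},
        }
        Path(schema_path).write_text(json.dumps(schema, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if "label" not in table.columns:
        raise SchemaError("feature table lacks a 'label' column")
    return table
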