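"""In-memory containers for multichannel inertial trial recordings.

A trial is one subject performing one task of the clinical test battery while
wearing eight body-worn inertial sensors (both feet, both shanks, both thighs,
pelvis/low back, thorax/sternum).  Each sensor contributes three channel
blocks — segment angle (deg), angular velocity (deg/s) and linear acceleration
(m/s^2) — each with three axes in the subject frame:

    axis 0: anterior (+forward)
    axis 1: rightward (+right, i.e. medio-lateral)
    axis 2: downward  (+down, i.e. vertical)

Angular-velocity axes are rotations about the same three axes, so column 1 is
pitch (forward lean) and column 2 is yaw (turning).  Linear acceleration is
the movement component only (gravity removed), which is what the sway and
gait summaries downstream operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np

#: Canonical sensor placement labels, in a fixed order.
SENSORS = (
    "foot_L",
    "foot_R",
    "shank_L",
    "shank_R",
    "thigh_L",
    "thigh_R",
    "pelvis",
    "thorax",
)

#: Channel block names within each sensor.
CHANNELS = ("angle", "angular_velocity", "linear_acceleration")

#: The five base tasks of the test battery.
TASKS = ("BAL_EO", "BAL_CE", "TUG", "MWT10", "STS")

#: The ten task variants (each base task with and without the cognitive load).
TASK_VARIANTS = tuple(
    f"{task}_{cond}" for task in TASKS for cond in ("single", "dual")
)


def task_variant(task: str, dual: bool) -> str:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return f"{task}_{'dual' if dual else 'single'}"


@dataclass
class SensorBlock:
    """One sensor's channels for a trial; arrays are (n_samples, 3)."""

    angle: np.ndarray
    angular_velocity: np.ndarray
    linear_acceleration: np.ndarray

    def __post_init__(self) -> None:
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be (n, 3), got {arr.shape}")
            setattr(self, name, arr)
        lengths = {getattr(self, name).shape[0] for name in CHANNELS}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ within sensor: {lengths}")

    @property
    def n_samples(self) -> int:
        return self.angle.shape[0]


@dataclass
class TrialRecording:
    """Multichannel 60 Hz recording of one subject x one task x 8 sensors."""

    subject_id: str
    task_id: str  # one of TASK_VARIANTS
    fs_hz: float
    sensors: Dict[str, SensorBlock]

    def __post_init__(self) -> None:
        if self.task_id not in TASK_VARIANTS:
            raise ValueError(
                f"task_id {self.task_id!r} not in battery {TASK_VARIANTS}"
            )
        unknown = set(self.sensors) - set(SENSORS)
        if unknown:
            raise ValueError(f"unknown sensor labels: {sorted(unknown)}")
        lengths = {blk.n_samples for blk in self.sensors.values()}
        if len(lengths) > 1:
            raise ValueError(f"sensors disagree on trial length: {lengths}")

    @property
    def task(self) -> str:
        return self.task_id.rsplit("_", 1)[0]

    @property
    def dual(self) -> bool:
        return self.task_id.endswith("_dual")

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class GroundTruthAnnotation:
    """Simulator-emitted truth for one trial.

    ``events`` holds the true event times in seconds from trial start, keyed by
    event kind (``hs_L``, ``to_R``, ``tug_boundaries``, ``sts_cycles`` …);
    ``params`` holds the generator parameters actually used (target sway std
    per sensor/axis, mean stride time, phase durations, …) so detectors and
    feature extractors can be validated against what was scripted.
    """

    subject_id: str
    task_id: str
    events: Dict[str, object] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)

    def event_array(self, key: str) -> np.ndarray:
        return np.asarray(self.events.get(key, ()), dtype=float)


def validate_annotation(ann: GroundTruthAnnotation, duration_s: float) -> None:
    """Check that every annotated event time lies inside the trial."""
    for key, val in ann.events.items():
        arr = np.asarray(val, dtype=float).ravel()
        if arr.size and (arr.min() < 0 or arr.max() > duration_s + 1e-9):
            raise ValueError(
                f"annotation {key} has events outside [0, {duration_s:.3f}] s"
            )


TrialMap = Mapping[str, TrialRecording]
TrialList = List[TrialRecording]
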