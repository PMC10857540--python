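"""The 92-feature pool: catalogue, per-test extractors and table assembly.

The pool decomposes as 42 single-task motion features (7 balance eyes-open +
7 balance eyes-closed + 10 TUG + 8 ten-metre-walk + 10 sit-to-stand), the
same 42 recomputed on the dual-task trials (names prefixed ``Dual_``), and 8
clinical/demographic features.  Units: durations s, cadence steps/min,
accelerations m/s^2, angular velocities deg/s.

Each catalogue entry records which sensor placements the feature needs (as a
tuple of alternative placement sets — e.g. step counts can come from shanks
or from feet); the sensor-configuration search filters on this map.  Clinical
entries need no sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import FilterSpec, filter_trial, resultant, sway_summary
from .recording import GroundTruthAnnotation, TrialRecording
from .segmentation import (
    GaitEvents,
    SegmentationParams,
    StsCycles,
    TugEvents,
    detect_gait_events,
    detect_sts_cycles,
    segment_tug,
)
from .simulate import SubjectProfile


class FeatureExtractionError(RuntimeError):
    """A feature could not be computed; message names feature and cause."""


Requirement = Tuple[FrozenSet[str], ...]  # alternatives; any subset suffices

_FEET = frozenset({"foot_L", "foot_R"})
_SHANKS = frozenset({"shank_L", "shank_R"})
_THIGHS = frozenset({"thigh_L", "thigh_R"})
_SHANKS_OR_FEET: Requirement = (_SHANKS, _FEET)
_TUG_CORE: Requirement = (frozenset({"thorax"}) | _FEET,)


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    task: str  # base task id, "" for clinical
    dual: bool
    requires: Requirement  # empty tuple => always available (clinical)

    @property
    def clinical(self) -> bool:
        return self.task == ""


_BALANCE_DESCRIPTORS: Tuple[Tuple[str, Requirement], ...] = (
    ("Thorax Linear Acc 1", (frozenset({"thorax"}),)),
    ("Thorax Linear Acc 2", (frozenset({"thorax"}),)),
    ("Thorax Linear Acc 3", (frozenset({"thorax"}),)),
    ("Thorax Linear Acc 4", (frozenset({"thorax"}),)),
    ("Pelvic Linear Acc 4", (frozenset({"pelvis"}),)),
    ("Right Thigh Linear Acc 4", (frozenset({"thigh_R"}),)),
    ("Left Thigh Linear Acc 4", (frozenset({"thigh_L"}),)),
)

_TUG_DESCRIPTORS: Tuple[Tuple[str, Requirement], ...] = (
    ("TUG_Time", _TUG_CORE),
    ("TUG_Sit to Stand", _TUG_CORE),
    ("TUG_Walk toward Cone", _TUG_CORE),
    ("TUG_Turn around the Cone", _TUG_CORE),
    ("TUG_Walk toward Chair", _TUG_CORE),
    ("TUG_Turn and Sit", _TUG_CORE),
    ("TUG_Steps toward Cone", _SHANKS_OR_FEET),
    ("TUG_Steps toward Chair", _SHANKS_OR_FEET),
    ("TUG_Cadence toward Cone", _SHANKS_OR_FEET),
    ("TUG_Cadence toward Chair", _SHANKS_OR_FEET),
)

_MWT_DESCRIPTORS: Tuple[Tuple[str, Requirement], ...] = tuple(
    (name, _SHANKS_OR_FEET)
    for name in (
        "10MWT_Walk Time", "10MWT_Step", "10MWT_Cadence",
        "10MWT_mean Swing Total", "10MWT_std Swing Total",
        "10MWT_Single Support", "10MWT_Stride Duration",
        "10MWT_std Stride Duration",
    )
)

_STS_DESCRIPTORS: Tuple[Tuple[str, Requirement], ...] = (
    ("STS_Time", (_THIGHS,)),
    ("STS_Mean Sit to Stand", (_THIGHS,)),
    ("STS_Mean Stand to Sit", (_THIGHS,)),
    ("STS_Thorax Ang Vel", (_THIGHS | {"thorax"},)),
    ("STS_Pelvic Ang Vel", (_THIGHS | {"pelvis"},)),
    ("STS_std STS", (_THIGHS,)),
    ("STS_std Sit to Stand", (_THIGHS,)),
    ("STS_std Stand to Sit", (_THIGHS,)),
    ("STS_std Thorax Ang Vel", (_THIGHS | {"thorax"},)),
    ("STS_std Pelvic Ang Vel", (_THIGHS | {"pelvis"},)),
)

CLINICAL_FEATURES = (
    "BMI", "Gender", "Age", "Feel Unsteady", "Worried when Walking",
    "Joint Pain", "Number Neurological Disease beside Stroke",
    "Fear of Fall (FES Questionnaire)",
)


def build_catalogue() -> List[CatalogueEntry]:
    """The ordered 92-entry feature catalogue (42 single + 42 dual + 8 clinical)."""
    motion: List[CatalogueEntry] = []
    for desc, req in _BALANCE_DESCRIPTORS:
        motion.append(CatalogueEntry(f"Balance_{desc}", "BAL_EO", False, req))
    for desc, req in _BALANCE_DESCRIPTORS:
        motion.append(CatalogueEntry(f"CE_Balance_{desc}", "BAL_CE", False, req))
    for name, req in _TUG_DESCRIPTORS:
        motion.append(CatalogueEntry(name, "TUG", False, req))
    for name, req in _MWT_DESCRIPTORS:
        motion.append(CatalogueEntry(name, "MWT10", False, req))
    for name, req in _STS_DESCRIPTORS:
        motion.append(CatalogueEntry(name, "STS", False, req))
    dual = [CatalogueEntry(f"Dual_{e.name}", e.task, True, e.requires)
            for e in motion]
    clinical = [CatalogueEntry(name, "", False, ()) for name in CLINICAL_FEATURES]
    catalogue = motion + dual + clinical
    assert len(catalogue) == 92
    return catalogue


CATALOGUE: List[CatalogueEntry] = build_catalogue()
FEATURE_NAMES: Tuple[str, ...] = tuple(e.name for e in CATALOGUE)
MOTION_FEATURES: Tuple[str, ...] = tuple(e.name for e in CATALOGUE if not e.clinical)
DUAL_FEATURES: Tuple[str, ...] = tuple(e.name for e in CATALOGUE if e.dual)


def catalogue_index(name: str) -> int:
    return FEATURE_NAMES.index(name)


# --------------------------------------------------------------------------
# per-test extractors (all expect a low-passed trial)
# --------------------------------------------------------------------------


def _prefix(eyes: str, dual: bool) -> str:
    pre = "Dual_" if dual else ""
    if eyes == "closed":
        pre += "CE_"
    return pre


def balance_features(trial: TrialRecording, eyes: str, dual: bool
                     ) -> Dict[str, float]:
    """Seven sway summaries: thorax axes 1-3 + resultant, and the resultant
    sway of pelvis and both thighs."""
    pre = _prefix(eyes, dual)
    out: Dict[str, float] = {}
    needed = {"thorax": "Thorax", "pelvis": "Pelvic", "thigh_R": "Right Thigh",
              "thigh_L": "Left Thigh"}
    for sensor, label in needed.items():
        if sensor not in trial.sensors:
            raise FeatureExtractionError(
                f"{pre}Balance_{label} Linear Acc: sensor {sensor} missing"
            )
    acc = trial.sensors["thorax"].linear_acceleration
    for axis in range(3):
        out[f"{pre}Balance_Thorax Linear Acc {axis + 1}"] = sway_summary(acc[:, axis])
    out[f"{pre}Balance_Thorax Linear Acc 4"] = sway_summary(
        resultant(acc[:, 0], acc[:, 1], acc[:, 2])
    )
    for sensor, label in (("pelvis", "Pelvic"), ("thigh_R", "Right Thigh"),
                          ("thigh_L", "Left Thigh")):
        a = trial.sensors[sensor].linear_acceleration
        out[f"{pre}Balance_{label} Linear Acc 4"] = sway_summary(
            resultant(a[:, 0], a[:, 1], a[:, 2])
        )
    return out


def _steps_in(events: GaitEvents, start: float, stop: float) -> int:
    return int(sum(((hs >= start) & (hs < stop)).sum()
                   for hs in events.hs.values()))


def tug_features(trial: TrialRecording, tug_events: TugEvents,
                 gait_events: GaitEvents) -> Dict[str, float]:
    """Total time, the five phase durations, and step counts / cadences of
    the two walk phases (cadence = 60 * steps / phase duration)."""
    if not tug_events.valid:
        raise FeatureExtractionError(
            "TUG segmentation invalid: " + "; ".join(tug_events.diagnostics)
        )
    pre = "Dual_" if trial.dual else ""
    t = tug_events.t
    d = tug_events.phase_durations
    steps_cone = _steps_in(gait_events, t[1], t[2])
    steps_chair = _steps_in(gait_events, t[3], t[4])
    return {
        f"{pre}TUG_Time": float(t[5] - t[0]),
        f"{pre}TUG_Sit to Stand": float(d[0]),
        f"{pre}TUG_Walk toward Cone": float(d[1]),
        f"{pre}TUG_Turn around the Cone": float(d[2]),
        f"{pre}TUG_Walk toward Chair": float(d[3]),
        f"{pre}TUG_Turn and Sit": float(d[4]),
        f"{pre}TUG_Steps toward Cone": float(steps_cone),
        f"{pre}TUG_Steps toward Chair": float(steps_chair),
        f"{pre}TUG_Cadence toward Cone": 60.0 * steps_cone / float(d[1]),
        f"{pre}TUG_Cadence toward Chair": 60.0 * steps_chair / float(d[3]),
    }


def _swing_stride_durations(events: GaitEvents
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled swing (TO -> next HS, same foot) and stride (HS -> HS) durations."""
    swings, strides = [], []
    for foot in events.hs:
        hs = np.asarray(events.hs[foot])
        to = np.asarray(events.to.get(foot, ()))
        strides.extend(np.diff(hs).tolist())
        for t0 in to:
            nxt = hs[hs > t0]
            if nxt.size:
                swings.append(float(nxt[0] - t0))
    return np.asarray(swings), np.asarray(strides)


def walk_features(trial: TrialRecording, gait_events: GaitEvents
                  ) -> Dict[str, float]:
    """Eight 10MWT summaries from the detected gait events."""
    pre = "Dual_" if trial.dual else ""
    all_events = np.sort(np.concatenate(
        [np.asarray(v) for v in list(gait_events.hs.values())
         + list(gait_events.to.values()) if len(v)] or [np.empty(0)]
    ))
    swings, strides = _swing_stride_durations(gait_events)
    if strides.size < 2 or all_events.size < 4:
        raise FeatureExtractionError(
            f"10MWT: need >= 3 strides, got {strides.size + 1} stride intervals"
        )
    walk_time = float(all_events[-1] - all_events[0])
    steps = gait_events.n_steps()
    # single support = contralateral swing; pooled over feet it matches the
    # pooled swing mean, computed independently here via the contralateral map
    singles = []
    feet = list(gait_events.hs)
    for foot in feet:
        others = [f for f in feet if f != foot]
        if not others:
            continue
        other = others[0]
        to = np.asarray(gait_events.to.get(other, ()))
        hs = np.asarray(gait_events.hs.get(other, ()))
        for t0 in to:
            nxt = hs[hs > t0]
            if nxt.size:
                singles.append(float(nxt[0] - t0))
    single_support = float(np.mean(singles)) if singles else float(np.mean(swings))
    return {
        f"{pre}10MWT_Walk Time": walk_time,
        f"{pre}10MWT_Step": float(steps),
        f"{pre}10MWT_Cadence": 60.0 * steps / walk_time,
        f"{pre}10MWT_mean Swing Total": float(np.mean(swings)),
        f"{pre}10MWT_std Swing Total": float(np.std(swings)),
        f"{pre}10MWT_Single Support": single_support,
        f"{pre}10MWT_Stride Duration": float(np.mean(strides)),
        f"{pre}10MWT_std Stride Duration": float(np.std(strides)),
    }


def sts_features(trial: TrialRecording, cycles: StsCycles) -> Dict[str, float]:
    """Ten sit-to-stand summaries: cycle timing and trunk/pelvis angular
    velocity peaks (mean and std over cycles)."""
    if cycles.mismatch:
        raise FeatureExtractionError(
            "STS cycle count mismatch: " + "; ".join(cycles.diagnostics)
        )
    if cycles.n_cycles < 2:
        raise FeatureExtractionError(
            f"STS: need >= 2 cycles for dispersion features, got {cycles.n_cycles}"
        )
    pre = "Dual_" if trial.dual else ""
    c = cycles.cycles
    dur = c[:, 3] - c[:, 0]
    s2s = c[:, 1] - c[:, 0]
    st2s = c[:, 3] - c[:, 2]
    fs = trial.fs_hz
    peaks = {"thorax": [], "pelvis": []}
    for sensor in peaks:
        if sensor not in trial.sensors:
            raise FeatureExtractionError(f"STS angular velocity: {sensor} missing")
        w = trial.sensors[sensor].angular_velocity
        mag = resultant(w[:, 0], w[:, 1], w[:, 2])
        for (c0, _, _, c3) in c:
            lo, hi = int(c0 * fs), min(len(mag), int(np.ceil(c3 * fs)) + 1)
            peaks[sensor].append(float(mag[lo:hi].max()))
    return {
        f"{pre}STS_Time": float(c[-1, 3] - c[0, 0]),
        f"{pre}STS_Mean Sit to Stand": float(np.mean(s2s)),
        f"{pre}STS_Mean Stand to Sit": float(np.mean(st2s)),
        f"{pre}STS_Thorax Ang Vel": float(np.mean(peaks["thorax"])),
        f"{pre}STS_Pelvic Ang Vel": float(np.mean(peaks["pelvis"])),
        f"{pre}STS_std STS": float(np.std(dur)),
        f"{pre}STS_std Sit to Stand": float(np.std(s2s)),
        f"{pre}STS_std Stand to Sit": float(np.std(st2s)),
        f"{pre}STS_std Thorax Ang Vel": float(np.std(peaks["thorax"])),
        f"{pre}STS_std Pelvic Ang Vel": float(np.std(peaks["pelvis"])),
    }


def clinical_features(profile: SubjectProfile) -> Dict[str, float]:
    """Eight clinical/demographic features (gender encoded M=0/F=1)."""
    return {
        "BMI": float(profile.bmi),
        "Gender": float(profile.gender == "F"),
        "Age": float(profile.age),
        "Feel Unsteady": float(profile.feel_unsteady),
        "Worried when Walking": float(profile.worried_when_walking),
        "Joint Pain": float(profile.joint_pain),
        "Number Neurological Disease beside Stroke": float(profile.n_neuro_comorbid),
        "Fear of Fall (FES Questionnaire)": float(profile.fes_short),
    }


# --------------------------------------------------------------------------
# trial -> features dispatch and table assembly
# --------------------------------------------------------------------------


def _foot_resultants(trial: TrialRecording, sensors: Sequence[str]
                     ) -> Dict[str, np.ndarray]:
    out = {}
    for s in sensors:
        a = trial.sensors[s].linear_acceleration
        out[s.rsplit("_", 1)[1]] = resultant(a[:, 0], a[:, 1], a[:, 2])
    return out


#: Channels each task's extractor actually reads (filtering is restricted to
#: these; the extractors never touch the remaining raw channels).
_TASK_CHANNELS = {
    "BAL_EO": {s: {"linear_acceleration"}
               for s in ("thorax", "pelvis", "thigh_L", "thigh_R")},
    "BAL_CE": {s: {"linear_acceleration"}
               for s in ("thorax", "pelvis", "thigh_L", "thigh_R")},
    "TUG": {"thorax": {"angular_velocity"},
            "foot_L": {"linear_acceleration"},
            "foot_R": {"linear_acceleration"}},
    "MWT10": {"shank_L": {"linear_acceleration"},
              "shank_R": {"linear_acceleration"}},
    "STS": {"thigh_L": {"angular_velocity"},
            "thigh_R": {"angular_velocity"},
            "thorax": {"angular_velocity"},
            "pelvis": {"angular_velocity"}},
}


def extract_trial_features(trial: TrialRecording,
                           filter_spec: Optional[FilterSpec] = None,
                           seg_params: Optional[SegmentationParams] = None
                           ) -> Dict[str, float]:
    """Filter one trial, segment it as its task requires, extract features."""
    filtered = filter_trial(trial, filter_spec,
                            channels=_TASK_CHANNELS[trial.task])
    task = filtered.task
    if task in ("BAL_EO", "BAL_CE"):
        eyes = "open" if task == "BAL_EO" else "closed"
        return balance_features(filtered, eyes, filtered.dual)
    if task == "TUG":
        feet = _foot_resultants(filtered, ("foot_L", "foot_R"))
        tug = segment_tug(filtered.sensors["thorax"].angular_velocity, feet,
                          filtered.fs_hz, seg_params)
        gait = detect_gait_events(feet, filtered.fs_hz, params=seg_params)
        return tug_features(filtered, tug, gait)
    if task == "MWT10":
        shanks = _foot_resultants(filtered, ("shank_L", "shank_R"))
        gait = detect_gait_events(shanks, filtered.fs_hz, params=seg_params)
        return walk_features(filtered, gait)
    if task == "STS":
        thigh = 0.5 * (filtered.sensors["thigh_L"].angular_velocity[:, 1]
                       + filtered.sensors["thigh_R"].angular_velocity[:, 1])
        cycles = detect_sts_cycles(thigh, filtered.fs_hz,
                                   expected_cycles=None, params=seg_params)
        return sts_features(filtered, cycles)
    raise FeatureExtractionError(f"no extractor for task {task!r}")


def assemble_feature_table(profiles: Sequence[SubjectProfile],
                           trials: Sequence[TrialRecording],
                           filter_spec: Optional[FilterSpec] = None,
                           seg_params: Optional[SegmentationParams] = None
                           ) -> pd.DataFrame:
    """Build the subjects x 92 feature table (+ binary ``label`` column).

    Any failed extraction raises :class:`FeatureExtractionError` naming the
    subject, task and feature — the table never contains silent NaNs.
    """
    by_subject: Dict[str, List[TrialRecording]] = {}
    for tr in trials:
        by_subject.setdefault(tr.subject_id, []).append(tr)
    rows = []
    for profile in profiles:
        subject_trials = by_subject.get(profile.subject_id, [])
        if len(subject_trials) != 10:
            raise FeatureExtractionError(
                f"{profile.subject_id}: expected 10 trials, got {len(subject_trials)}"
            )
        values: Dict[str, float] = {}
        for tr in subject_trials:
            try:
                values.update(extract_trial_features(tr, filter_spec, seg_params))
            except FeatureExtractionError as exc:
                raise FeatureExtractionError(
                    f"{profile.subject_id}/{tr.task_id}: {exc}"
                ) from exc
        values.update(clinical_features(profile))
        missing = [n for n in FEATURE_NAMES if n not in values]
        if missing:
            raise FeatureExtractionError(
                f"{profile.subject_id}: features not produced: {missing[:5]}"
            )
        row = {name: values[name] for name in FEATURE_NAMES}
        row["label"] = int(profile.is_faller)
        rows.append(row)
    table = pd.DataFrame(rows, index=[p.subject_id for p in profiles])
    table.index.name = "subject_id"
    return table
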