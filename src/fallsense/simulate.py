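"""Synthetic cohorts of stroke survivors performing the clinical test battery.

No public recording of the instrumented battery exists, so every downstream
stage is exercised against simulated subjects.  The simulator is a *validation
scaffold*, not a biomechanical model: each task is scripted from deterministic
motifs with an unambiguous ground truth —

* quiet standing: zero-mean band-limited stochastic sway (white noise through
  a low-pass shaping filter, rescaled to an exact target std per axis);
* walking: one dominant symmetric impact transient per heel strike and a
  smaller one per toe off on the foot/shank channels, with stride times drawn
  around a subject-specific mean;
* transitions (TUG sit-to-stand/turns, STS cycles): Gaussian angular-velocity
  lobes whose 10 %-of-peak crossings coincide exactly with the scripted phase
  boundaries (sigma = duration / 4.29), so onset/offset detectors have a
  well-defined truth;
* additive white sensor noise on every channel.

Group structure.  Fallers and non-fallers differ only through the effect
multipliers in :class:`CohortSpec` (larger sway, slower gait, longer
transitions, larger dual-task cost).  With all multipliers at 1 the two
groups are exchangeable by construction ("null mode").  A per-faller
*dual-task unmasking* trait gamma in [0, 0.5] splits the sway deficit across
task conditions: the sway multiplier is F**(1-gamma) on single-task trials
and F**(1+gamma) on dual-task trials, reflecting deficits that only surface
under divided attention.  Between-subject heterogeneity comes from a latent
mobility scalar plus log-normal subject, per-trial ("day form") and
per-parameter factors; all magnitudes are listed in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .recording import (
    GroundTruthAnnotation,
    SENSORS,
    SensorBlock,
    TASKS,
    TrialRecording,
    task_variant,
)


class ConfigurationError(ValueError):
    """Invalid cohort/generator configuration; message names the field."""


#: Default group effect multipliers (see docs/methods.md).
DEFAULT_EFFECTS: Dict[str, float] = {
    "sway_std_faller": 1.5,
    "gait_speed_faller": 0.8,
    "transition_time_faller": 1.3,
    "dual_task_cost_faller": 1.2,
    "dual_task_cost_nonfaller": 1.05,
}

# ----- scripted base parameters (the "average non-faller", single task) -----

#: Thorax sway acceleration std (m/s^2) per axis: anterior, right, down.
BASE_SWAY_STD = (0.08, 0.06, 0.04)
#: Sensor scaling of the sway magnitude relative to the thorax.
SWAY_SENSOR_SCALE = {"thorax": 1.0, "pelvis": 0.8, "thigh_L": 0.5, "thigh_R": 0.5}
SWAY_SENSORS = tuple(SWAY_SENSOR_SCALE)
CLOSED_EYES_MULT = 1.35  # Romberg-like sway increase with eyes closed

BASE_STRIDE_TIME_S = 1.15
STRIDE_CV = 0.04  # stride-to-stride timing variability
SWING_FRAC = 0.40  # swing = 40 % of the gait cycle
BASE_GAIT_SPEED_MS = 1.0

HS_AMP = 4.0  # heel-strike transient, m/s^2 (before filtering)
TO_AMP = 1.5  # toe-off transient, m/s^2
IMPACT_SIGMA_S = 0.025

TUG_BASE = {"sit_to_stand_s": 1.6, "turn_s": 2.0, "turn_sit_s": 2.6, "walk_m": 3.0}
STS_BASE = {"rise_s": 1.2, "stand_s": 0.5, "descend_s": 1.3, "sit_gap_s": 0.8,
            "n_cycles": 5}
LOBE_AMP = {
    "tug_pitch": 60.0,  # deg/s, thorax pitch during sit-to-stand
    "tug_pitch_sit": 55.0,
    "tug_yaw": 80.0,  # thorax yaw during turns
    "tug_yaw_back": 75.0,
    "sts_thigh": 100.0,
    "sts_thigh_down": 90.0,
    "sts_thorax": 45.0,
    "sts_pelvis": 60.0,
}

# Between-subject / between-trial variability (log-scale std); frozen design
# values, see docs/methods.md.
SUBJECT_SWAY_SD = 0.12
SUBJECT_PACE_SD = 0.25
STRIDE_LENGTH_SD = 0.08
AXIS_FACTOR_SD = 0.10
TRIAL_FACTOR_SD = 0.12
PARAM_JITTER_SD = 0.05
AMP_JITTER_SD = 0.08
MOBILITY_RANGE = (0.6, 1.0)
UNMASKING_RANGE = (0.0, 0.5)

# Clinical table sampling targets (printed group statistics).
CLINICAL_STATS = {
    "faller": {
        "n_ref": 11,
        "p_female": 7 / 11,
        "age": (64.1, 12.3),
        "height_cm": (172.7, 8.0),
        "weight_kg": (84.0, 13.3),
        "fes": (13.1, 5.1),
        "p_poor_vision": 1 / 11,
        "p_joint_pain": 8 / 11,
        "p_feel_unsteady": 9 / 11,
        "p_worried": 7 / 11,
        "p_joint_replacement": 3 / 11,
    },
    "nonfaller": {
        "n_ref": 10,
        "p_female": 3 / 10,
        "age": (67.6, 7.1),
        "height_cm": (175.0, 9.1),
        "weight_kg": (90.8, 16.2),
        "fes": (9.1, 3.0),
        "p_poor_vision": 1 / 10,
        "p_joint_pain": 6 / 10,
        "p_feel_unsteady": 6 / 10,
        "p_worried": 3 / 10,
        "p_joint_replacement": 3 / 10,
    },
}

#: Gaussian lobes whose 10 %-of-peak crossings sit at the interval boundaries.
LOBE_SIGMA_DIV = 2.0 * math.sqrt(2.0 * math.log(10.0))  # ~4.292


@dataclass(frozen=True)
class CohortSpec:
    """Cohort configuration (sizes, sampling rate, effects, noise, seed)."""

    n_fallers: int = 11
    n_nonfallers: int = 10
    fs_hz: float = 60.0
    seed: int = 0
    effect_profile: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_level: float = 0.02  # sensor noise std (m/s^2 and deg/s)

    def validate(self) -> None:
        if self.n_fallers < 0:
            raise ConfigurationError("n_fallers must be >= 0")
        if self.n_nonfallers < 0:
            raise ConfigurationError("n_nonfallers must be >= 0")
        if self.fs_hz <= 10.0:
            raise ConfigurationError(
                "fs_hz must exceed twice the 5 Hz filter cutoff"
            )
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be >= 0")
        unknown = set(self.effect_profile) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ConfigurationError(
                f"effect_profile has unknown keys: {sorted(unknown)}"
            )
        for key, val in self.effect_profile.items():
            if not val > 0:
                raise ConfigurationError(f"effect_profile[{key!r}] must be > 0")

    @property
    def effects(self) -> Dict[str, float]:
        eff = dict(DEFAULT_EFFECTS)
        eff.update(self.effect_profile)
        return eff


@dataclass
class SubjectProfile:
    """One subject: demographics, questionnaire items and latent traits."""

    subject_id: str
    group: str  # "faller" | "nonfaller"
    age: float
    gender: str  # "M" | "F"
    height_cm: float
    weight_kg: float
    bmi: float
    feel_unsteady: int
    worried_when_walking: int
    joint_pain: int
    poor_vision: int
    joint_replacement: int
    n_neuro_comorbid: int
    fes_short: int
    latent_mobility: float  # (0, 1]; lower = more impaired
    latents: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("faller", "nonfaller"):
            raise ConfigurationError(f"group must be faller/nonfaller, got {self.group}")
        if not 7 <= self.fes_short <= 28:
            raise ConfigurationError("fes_short must lie in [7, 28]")
        expected_bmi = self.weight_kg / (self.height_cm / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 0.1:
            raise ConfigurationError("bmi inconsistent with height/weight")
        if not 0 < self.latent_mobility <= 1:
            raise ConfigurationError("latent_mobility must lie in (0, 1]")

    @property
    def is_faller(self) -> bool:
        return self.group == "faller"

    @property
    def difficulty(self) -> float:
        """Task-difficulty scalar: 1/sqrt(mobility), >= 1."""
        return self.latent_mobility ** -0.5


# --------------------------------------------------------------------------
# latent draws and effect arithmetic
# --------------------------------------------------------------------------


def _draw_profile(rng: np.random.Generator, subject_id: str, group: str
                  ) -> SubjectProfile:
    st = CLINICAL_STATS[group]
    gender = "F" if rng.random() < st["p_female"] else "M"
    age = float(np.clip(rng.normal(*st["age"]), 30.0, 95.0))
    height = float(np.clip(rng.normal(*st["height_cm"]), 145.0, 200.0))
    weight = float(np.clip(rng.normal(*st["weight_kg"]), 45.0, 140.0))
    bmi = weight / (height / 100.0) ** 2
    fes = int(np.clip(round(rng.normal(*st["fes"])), 7, 28))
    latents = {
        "sway_factor": float(rng.normal(0.0, SUBJECT_SWAY_SD)),
        "pace_factor": float(rng.normal(0.0, SUBJECT_PACE_SD)),
        # anthropometric stride-length variation, independent of pace
        "stride_length_factor": float(rng.normal(0.0, STRIDE_LENGTH_SD)),
        "unmasking": float(rng.uniform(*UNMASKING_RANGE)) if group == "faller" else 0.0,
        "axis_factors": {
            (sensor, axis): float(rng.normal(0.0, AXIS_FACTOR_SD))
            for sensor in SWAY_SENSORS
            for axis in range(3)
        },
    }
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        age=age,
        gender=gender,
        height_cm=height,
        weight_kg=weight,
        bmi=bmi,
        feel_unsteady=int(rng.random() < st["p_feel_unsteady"]),
        worried_when_walking=int(rng.random() < st["p_worried"]),
        joint_pain=int(rng.random() < st["p_joint_pain"]),
        poor_vision=int(rng.random() < st["p_poor_vision"]),
        joint_replacement=int(rng.random() < st["p_joint_replacement"]),
        n_neuro_comorbid=int(min(rng.poisson(0.4), 3)),
        fes_short=fes,
        latent_mobility=float(rng.uniform(*MOBILITY_RANGE)),
        latents=latents,
    )


def _sway_multiplier(profile: SubjectProfile, effects: Dict[str, float],
                     dual: bool) -> float:
    if profile.is_faller:
        gamma = float(profile.latents.get("unmasking", 0.0))
        F = effects["sway_std_faller"]
        expo = 1.0 + gamma if dual else 1.0 - gamma
        mult = F ** expo
        if dual:
            mult *= effects["dual_task_cost_faller"]
        return mult
    return effects["dual_task_cost_nonfaller"] if dual else 1.0


def _duration_multiplier(profile: SubjectProfile, effects: Dict[str, float],
                         dual: bool, transition: bool) -> float:
    mult = 1.0
    if profile.is_faller and transition:
        mult *= effects["transition_time_faller"]
    if dual:
        mult *= (effects["dual_task_cost_faller"] if profile.is_faller
                 else effects["dual_task_cost_nonfaller"])
    return mult


def _gait_pace(profile: SubjectProfile, effects: Dict[str, float], dual: bool,
               trial_factor: float) -> Tuple[float, float]:
    """(stride_time_s, gait_speed_m_s) for this subject/condition/trial."""
    slowness = math.exp(profile.latents["pace_factor"]) * profile.difficulty
    slowness *= trial_factor
    cost = (effects["dual_task_cost_faller"] if profile.is_faller
            else effects["dual_task_cost_nonfaller"]) if dual else 1.0
    speed_mult = effects["gait_speed_faller"] if profile.is_faller else 1.0
    stride = BASE_STRIDE_TIME_S * slowness * cost * speed_mult ** -0.5
    length_f = math.exp(profile.latents.get("stride_length_factor", 0.0))
    speed = BASE_GAIT_SPEED_MS * speed_mult * length_f / (slowness * cost)
    return stride, speed


# --------------------------------------------------------------------------
# signal-building primitives
# --------------------------------------------------------------------------


def _gauss_bump(arr: np.ndarray, fs: float, center_s: float, sigma_s: float,
                amp: float) -> None:
    """Add a Gaussian bump (in place) to a 1-D signal."""
    n = arr.shape[0]
    half = max(1, int(round(4 * sigma_s * fs)))
    c = center_s * fs
    lo = max(0, int(math.floor(c)) - half)
    hi = min(n, int(math.ceil(c)) + half + 1)
    if lo >= hi:
        return
    idx = np.arange(lo, hi)
    arr[lo:hi] += amp * np.exp(-0.5 * ((idx - c) / (sigma_s * fs)) ** 2)


def _phase_lobe(arr: np.ndarray, fs: float, start_s: float, end_s: float,
                amp: float) -> None:
    """Gaussian lobe whose 10 %-of-peak crossings are exactly start/end."""
    dur = end_s - start_s
    _gauss_bump(arr, fs, (start_s + end_s) / 2.0, dur / LOBE_SIGMA_DIV, amp)


from functools import lru_cache


@lru_cache(maxsize=8)
def _sway_sos(fs: float):
    from scipy import signal as _sig

    return _sig.butter(2, 1.2, btype="low", fs=fs, output="sos")


def _shaped_sway(rng: np.random.Generator, n: int, fs: float,
                 target_std: float) -> np.ndarray:
    """Band-limited noise rescaled to an exact target std (postural sway)."""
    from scipy import signal as _sig

    white = rng.standard_normal(n + 256)
    shaped = _sig.sosfilt(_sway_sos(fs), white)[256:]
    shaped = shaped - shaped.mean()
    sd = shaped.std()
    if sd == 0:  # pragma: no cover - degenerate draw
        return np.zeros(n)
    return shaped * (target_std / sd)


def _empty_channels(n: int) -> Dict[str, Dict[str, np.ndarray]]:
    return {
        s: {"angular_velocity": np.zeros((n, 3)), "linear_acceleration": np.zeros((n, 3))}
        for s in SENSORS
    }


def _assemble_trial(subject_id: str, task_id: str, fs: float,
                    channels: Dict[str, Dict[str, np.ndarray]],
                    rng: np.random.Generator, noise_level: float
                    ) -> TrialRecording:
    """Integrate angles, add sensor noise, wrap into a TrialRecording."""
    sensors = {}
    for name, chans in channels.items():
        angvel = chans["angular_velocity"]
        acc = chans["linear_acceleration"]
        angle = np.cumsum(angvel, axis=0) / fs
        if noise_level > 0:
            angle = angle + noise_level * rng.standard_normal(angle.shape)
            angvel = angvel + noise_level * rng.standard_normal(angvel.shape)
            acc = acc + noise_level * rng.standard_normal(acc.shape)
        sensors[name] = SensorBlock(
            angle=angle, angular_velocity=angvel, linear_acceleration=acc
        )
    return TrialRecording(subject_id=subject_id, task_id=task_id, fs_hz=fs,
                          sensors=sensors)


# --------------------------------------------------------------------------
# task generators
# --------------------------------------------------------------------------


def simulate_balance(profile: SubjectProfile, eyes: str, dual: bool,
                     duration_s: float = 30.0, seed=0, fs_hz: float = 60.0,
                     effects: Optional[Dict[str, float]] = None,
                     noise_level: float = 0.02
                     ) -> Tuple[TrialRecording, GroundTruthAnnotation]:
    """Quiet-standing trial: stochastic sway on trunk/pelvis/thigh channels.

    The target sway std per sensor/axis (after all multipliers) is recorded in
    the annotation; with ``noise_level=0`` the empirical std of each sway
    channel equals the target exactly by construction.
    """
    if eyes not in ("open", "closed"):
        raise ConfigurationError(f"eyes must be open/closed, got {eyes!r}")
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be > 0")
    effects = dict(DEFAULT_EFFECTS, **(effects or {}))
    rng = np.random.default_rng(seed)
    fs = fs_hz
    n = int(round(duration_s * fs))
    task = "BAL_EO" if eyes == "open" else "BAL_CE"
    task_id = task_variant(task, dual)

    trial_factor = math.exp(rng.normal(0.0, TRIAL_FACTOR_SD))
    group_mult = _sway_multiplier(profile, effects, dual)
    ce_mult = CLOSED_EYES_MULT if eyes == "closed" else 1.0
    subj = math.exp(profile.latents["sway_factor"]) * profile.difficulty

    channels = _empty_channels(n)
    targets: Dict[str, Dict[str, float]] = {}
    for sensor in SWAY_SENSORS:
        targets[sensor] = {}
        for axis in range(3):
            ax_f = math.exp(profile.latents["axis_factors"][(sensor, axis)])
            jitter = math.exp(rng.normal(0.0, PARAM_JITTER_SD))
            target = (BASE_SWAY_STD[axis] * SWAY_SENSOR_SCALE[sensor]
                      * subj * ax_f * trial_factor * jitter
                      * ce_mult * group_mult)
            channels[sensor]["linear_acceleration"][:, axis] = _shaped_sway(
                rng, n, fs, target
            )
            targets[sensor][f"axis{axis + 1}"] = target

    trial = _assemble_trial(profile.subject_id, task_id, fs, channels, rng,
                            noise_level)
    ann = GroundTruthAnnotation(
        subject_id=profile.subject_id, task_id=task_id,
        events={},
        params={"sway_std": targets, "trial_factor": trial_factor,
                "duration_s": duration_s, "eyes": eyes, "dual": dual},
    )
    return trial, ann


def _script_gait(rng: np.random.Generator, start_s: float, n_strides: int,
                 stride_mean: float) -> Dict[str, np.ndarray]:
    """Alternating heel-strike/toe-off schedules for both feet.

    Left heel strikes at ``start_s`` and every stride thereafter; the right
    foot is offset by half a stride; each toe off precedes its heel strike by
    the swing duration.
    """
    strides = stride_mean * (1.0 + STRIDE_CV * rng.standard_normal(n_strides))
    strides = np.clip(strides, 0.5 * stride_mean, 1.5 * stride_mean)
    hs_L = start_s + np.concatenate(([0.0], np.cumsum(strides[:-1])))
    hs_R = hs_L + strides / 2.0
    swings = SWING_FRAC * strides * (1.0 + 0.5 * STRIDE_CV
                                     * rng.standard_normal(n_strides))
    to_L = hs_L - swings
    to_R = hs_R - SWING_FRAC * strides * (1.0 + 0.5 * STRIDE_CV
                                          * rng.standard_normal(n_strides))
    return {"hs_L": hs_L, "hs_R": hs_R, "to_L": to_L, "to_R": to_R,
            "strides": strides}


def _place_foot_transients(channels, fs: float, rng: np.random.Generator,
                           events: Dict[str, np.ndarray]) -> None:
    """Impact bumps on foot and shank acceleration channels of each side."""
    for side in ("L", "R"):
        for sensor in (f"foot_{side}", f"shank_{side}"):
            acc = channels[sensor]["linear_acceleration"]
            for t in events[f"hs_{side}"]:
                amp = HS_AMP * math.exp(rng.normal(0.0, AMP_JITTER_SD))
                _gauss_bump(acc[:, 2], fs, t, IMPACT_SIGMA_S, 0.9 * amp)
                _gauss_bump(acc[:, 0], fs, t, IMPACT_SIGMA_S, 0.45 * amp)
            for t in events[f"to_{side}"]:
                amp = TO_AMP * math.exp(rng.normal(0.0, AMP_JITTER_SD))
                _gauss_bump(acc[:, 0], fs, t, IMPACT_SIGMA_S, 0.9 * amp)
                _gauss_bump(acc[:, 2], fs, t, IMPACT_SIGMA_S, 0.45 * amp)


def simulate_gait_stream(profile: SubjectProfile, n_strides: int, dual: bool,
                         seed=0, fs_hz: float = 60.0,
                         effects: Optional[Dict[str, float]] = None,
                         noise_level: float = 0.02,
                         task: str = "MWT10"
                         ) -> Tuple[TrialRecording, GroundTruthAnnotation]:
    """Straight-walking stream of ``n_strides`` strides per foot."""
    if n_strides < 1:
        raise ConfigurationError("n_strides must be >= 1")
    effects = dict(DEFAULT_EFFECTS, **(effects or {}))
    rng = np.random.default_rng(seed)
    fs = fs_hz
    trial_factor = math.exp(rng.normal(0.0, TRIAL_FACTOR_SD))
    stride_mean, speed = _gait_pace(profile, effects, dual, trial_factor)

    lead = 1.0
    events = _script_gait(rng, lead, n_strides, stride_mean)
    end_s = float(events["hs_R"][-1]) + 1.0
    n = int(round(end_s * fs))
    channels = _empty_channels(n)
    _place_foot_transients(channels, fs, rng, events)

    task_id = task_variant(task, dual)
    trial = _assemble_trial(profile.subject_id, task_id, fs, channels, rng,
                            noise_level)
    ann = GroundTruthAnnotation(
        subject_id=profile.subject_id, task_id=task_id,
        events={k: events[k] for k in ("hs_L", "hs_R", "to_L", "to_R")},
        params={"stride_mean_s": stride_mean, "gait_speed_ms": speed,
                "swing_frac": SWING_FRAC, "n_strides": n_strides,
                "trial_factor": trial_factor, "dual": dual},
    )
    return trial, ann


def simulate_10mwt(profile: SubjectProfile, dual: bool, seed=0,
                   fs_hz: float = 60.0,
                   effects: Optional[Dict[str, float]] = None,
                   noise_level: float = 0.02,
                   distance_m: float = 10.0
                   ) -> Tuple[TrialRecording, GroundTruthAnnotation]:
    """10 m straight walk: stride count covers the distance at true speed."""
    effects = dict(DEFAULT_EFFECTS, **(effects or {}))
    # Peek at the pace with the same seed stream the gait generator will use
    # so the stride count matches the walked distance.
    rng = np.random.default_rng(seed)
    trial_factor = math.exp(rng.normal(0.0, TRIAL_FACTOR_SD))
    stride_mean, speed = _gait_pace(profile, effects, dual, trial_factor)
    stride_length = speed * stride_mean
    n_strides = max(2, int(math.ceil(distance_m / stride_length)))
    trial, ann = simulate_gait_stream(
        profile, n_strides, dual, seed=seed, fs_hz=fs_hz, effects=effects,
        noise_level=noise_level, task="MWT10",
    )
    ann.params["distance_m"] = distance_m
    ann.params["stride_length_m"] = stride_length
    return trial, ann


def simulate_tug(profile: SubjectProfile, dual: bool, seed=0,
                 fs_hz: float = 60.0,
                 effects: Optional[Dict[str, float]] = None,
                 noise_level: float = 0.02,
                 turn_scale: float = 1.0
                 ) -> Tuple[TrialRecording, GroundTruthAnnotation]:
    """Timed-Up-and-Go trial scripted as five contiguous phases.

    quiet sit | sit-to-stand (thorax pitch lobe) | walk to the cone |
    turn (thorax yaw lobe) | walk back | turn-and-sit (yaw + pitch lobes).
    The six boundary times t1..t6 are the truth; the first heel strike of
    each walk phase falls exactly on the phase boundary.
    """
    effects = dict(DEFAULT_EFFECTS, **(effects or {}))
    rng = np.random.default_rng(seed)
    fs = fs_hz
    trial_factor = math.exp(rng.normal(0.0, TRIAL_FACTOR_SD))
    stride_mean, speed = _gait_pace(profile, effects, dual, trial_factor)
    trans = _duration_multiplier(profile, effects, dual, transition=True)
    slowness = math.exp(profile.latents["pace_factor"]) * profile.difficulty

    def dur(base: float) -> float:
        return (base * slowness * trial_factor * trans
                * math.exp(rng.normal(0.0, PARAM_JITTER_SD)))

    d1 = dur(TUG_BASE["sit_to_stand_s"])
    d3 = dur(TUG_BASE["turn_s"]) * turn_scale
    d5 = dur(TUG_BASE["turn_sit_s"])
    d_walk = TUG_BASE["walk_m"] / speed
    t1 = 1.0
    t2 = t1 + d1
    t3 = t2 + d_walk
    t4 = t3 + d3
    t5 = t4 + d_walk
    t6 = t5 + d5
    n = int(round((t6 + 1.0) * fs))
    channels = _empty_channels(n)

    thorax_w = channels["thorax"]["angular_velocity"]
    jit = lambda: math.exp(rng.normal(0.0, AMP_JITTER_SD))
    _phase_lobe(thorax_w[:, 1], fs, t1, t2, LOBE_AMP["tug_pitch"] * jit())
    _phase_lobe(thorax_w[:, 2], fs, t3, t4, LOBE_AMP["tug_yaw"] * jit())
    _phase_lobe(thorax_w[:, 2], fs, t5, t5 + 0.6 * d5,
                -LOBE_AMP["tug_yaw_back"] * jit())
    _phase_lobe(thorax_w[:, 1], fs, t5 + 0.45 * d5, t6,
                -LOBE_AMP["tug_pitch_sit"] * jit())

    # Walk-phase steps: alternate feet every half stride, first contact on the
    # phase boundary, no steps in the final 0.25 s before the next boundary.
    def walk_steps(start: float, stop: float) -> Dict[str, List[float]]:
        out: Dict[str, List[float]] = {"hs_L": [], "hs_R": [], "to_L": [], "to_R": []}
        t, side = start, "L"
        while t < stop - 0.25:
            out[f"hs_{side}"].append(t)
            out[f"to_{side}"].append(t - SWING_FRAC * stride_mean)
            t += stride_mean / 2.0
            side = "R" if side == "L" else "L"
        return out

    ev = {"hs_L": [], "hs_R": [], "to_L": [], "to_R": []}
    for start, stop in ((t2, t3), (t4, t5)):
        for key, vals in walk_steps(start, stop).items():
            ev[key].extend(vals)
    events = {k: np.asarray(v) for k, v in ev.items()}
    _place_foot_transients(channels, fs, rng, events)

    task_id = task_variant("TUG", dual)
    trial = _assemble_trial(profile.subject_id, task_id, fs, channels, rng,
                            noise_level)
    ann = GroundTruthAnnotation(
        subject_id=profile.subject_id, task_id=task_id,
        events=dict(events, tug_boundaries=np.array([t1, t2, t3, t4, t5, t6])),
        params={
            "phase_durations": {
                "sit_to_stand": d1, "walk_toward_cone": d_walk, "turn": d3,
                "walk_toward_chair": d_walk, "turn_and_sit": d5,
            },
            "total_time_s": t6 - t1, "stride_mean_s": stride_mean,
            "gait_speed_ms": speed, "trial_factor": trial_factor, "dual": dual,
        },
    )
    return trial, ann


def simulate_sts(profile: SubjectProfile, dual: bool, seed=0,
                 fs_hz: float = 60.0,
                 effects: Optional[Dict[str, float]] = None,
                 noise_level: float = 0.02,
                 n_cycles: Optional[int] = None
                 ) -> Tuple[TrialRecording, GroundTruthAnnotation]:
    """Five-repetition sit-to-stand: paired angular-velocity lobes per cycle.

    Each cycle is rise lobe | standing plateau | descent lobe on the thigh
    pitch channels, with co-occurring scaled lobes on thorax and pelvis;
    cycles are separated by quiet sitting gaps.  The truth lists the cycle
    quadruples (start, sit->stand end, stand->sit start, end).
    """
    effects = dict(DEFAULT_EFFECTS, **(effects or {}))
    rng = np.random.default_rng(seed)
    fs = fs_hz
    n_cycles = STS_BASE["n_cycles"] if n_cycles is None else int(n_cycles)
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    trial_factor = math.exp(rng.normal(0.0, TRIAL_FACTOR_SD))
    trans = _duration_multiplier(profile, effects, dual, transition=True)
    slowness = math.exp(profile.latents["pace_factor"]) * profile.difficulty

    cycles = []
    amps_thorax, amps_pelvis = [], []
    t = 1.0
    for _ in range(n_cycles):
        jit = lambda: math.exp(rng.normal(0.0, PARAM_JITTER_SD))
        rise = STS_BASE["rise_s"] * slowness * trial_factor * trans * jit()
        stand = STS_BASE["stand_s"] * slowness * trial_factor * jit()
        desc = STS_BASE["descend_s"] * slowness * trial_factor * trans * jit()
        start = t
        cycles.append((start, start + rise, start + rise + stand,
                       start + rise + stand + desc))
        t = cycles[-1][3] + STS_BASE["sit_gap_s"] * slowness * jit()
    n = int(round((cycles[-1][3] + 1.0) * fs))
    channels = _empty_channels(n)

    for (c0, c1, c2, c3) in cycles:
        a_th = LOBE_AMP["sts_thorax"] * math.exp(rng.normal(0.0, AMP_JITTER_SD))
        a_pv = LOBE_AMP["sts_pelvis"] * math.exp(rng.normal(0.0, AMP_JITTER_SD))
        amps_thorax.append(a_th)
        amps_pelvis.append(a_pv)
        for sensor, amp_up, amp_down in (
            ("thigh_L", LOBE_AMP["sts_thigh"], LOBE_AMP["sts_thigh_down"]),
            ("thigh_R", LOBE_AMP["sts_thigh"], LOBE_AMP["sts_thigh_down"]),
            ("thorax", a_th, 0.9 * a_th),
            ("pelvis", a_pv, 0.9 * a_pv),
        ):
            w = channels[sensor]["angular_velocity"]
            _phase_lobe(w[:, 1], fs, c0, c1, amp_up)
            _phase_lobe(w[:, 1], fs, c2, c3, -amp_down)

    task_id = task_variant("STS", dual)
    trial = _assemble_trial(profile.subject_id, task_id, fs, channels, rng,
                            noise_level)
    cyc = np.asarray(cycles)
    ann = GroundTruthAnnotation(
        subject_id=profile.subject_id, task_id=task_id,
        events={"sts_cycles": cyc},
        params={
            "n_cycles": n_cycles,
            "cycle_durations": (cyc[:, 3] - cyc[:, 0]).tolist(),
            "sit_to_stand_durations": (cyc[:, 1] - cyc[:, 0]).tolist(),
            "stand_to_sit_durations": (cyc[:, 3] - cyc[:, 2]).tolist(),
            "thorax_peak_angvel": amps_thorax,
            "pelvis_peak_angvel": amps_pelvis,
            "trial_factor": trial_factor, "dual": dual,
        },
    )
    return trial, ann


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

_TASK_SIMULATORS = {
    "BAL_EO": lambda p, dual, seed, fs, eff, nl: simulate_balance(
        p, "open", dual, seed=seed, fs_hz=fs, effects=eff, noise_level=nl),
    "BAL_CE": lambda p, dual, seed, fs, eff, nl: simulate_balance(
        p, "closed", dual, seed=seed, fs_hz=fs, effects=eff, noise_level=nl),
    "TUG": lambda p, dual, seed, fs, eff, nl: simulate_tug(
        p, dual, seed=seed, fs_hz=fs, effects=eff, noise_level=nl),
    "MWT10": lambda p, dual, seed, fs, eff, nl: simulate_10mwt(
        p, dual, seed=seed, fs_hz=fs, effects=eff, noise_level=nl),
    "STS": lambda p, dual, seed, fs, eff, nl: simulate_sts(
        p, dual, seed=seed, fs_hz=fs, effects=eff, noise_level=nl),
}


def generate_profiles(spec: CohortSpec) -> List[SubjectProfile]:
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    profiles = []
    for i in range(spec.n_fallers):
        profiles.append(_draw_profile(rng, f"F{i + 1:02d}", "faller"))
    for i in range(spec.n_nonfallers):
        profiles.append(_draw_profile(rng, f"N{i + 1:02d}", "nonfaller"))
    return profiles


def clinical_table(profiles: List[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "subject_id": p.subject_id, "group": p.group,
            "label": int(p.is_faller), "gender": p.gender, "age": p.age,
            "height_cm": p.height_cm, "weight_kg": p.weight_kg, "bmi": p.bmi,
            "feel_unsteady": p.feel_unsteady,
            "worried_when_walking": p.worried_when_walking,
            "joint_pain": p.joint_pain, "poor_vision": p.poor_vision,
            "joint_replacement": p.joint_replacement,
            "n_neuro_comorbid": p.n_neuro_comorbid, "fes_short": p.fes_short,
        })
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec):
    """Generate a full cohort: profiles, 10 trials/subject, truth, clinical table.

    Deterministic: identical spec (including seed) reproduces every array
    bit-identically.
    """
    spec.validate()
    if spec.n_fallers + spec.n_nonfallers == 0:
        raise ConfigurationError("n_fallers + n_nonfallers must be >= 1")
    profiles = generate_profiles(spec)
    trial_root = np.random.SeedSequence(spec.seed).spawn(2)[1]
    trial_seeds = trial_root.spawn(len(profiles) * len(_TASK_SIMULATORS) * 2)
    effects = spec.effects
    trials, annotations = [], []
    k = 0
    for profile in profiles:
        for task in TASKS:
            for dual in (False, True):
                sim = _TASK_SIMULATORS[task]
                trial, ann = sim(profile, dual, trial_seeds[k], spec.fs_hz,
                                 effects, spec.noise_level)
                trials.append(trial)
                annotations.append(ann)
                k += 1
    return profiles, trials, annotations, clinical_table(profiles)
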