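"""Event detection: gait events, TUG phase boundaries, STS cycles.

Three detectors, one per test, all operating on low-passed signals:

* heel-strike / toe-off from the resultant shank (or foot) acceleration —
  heel strikes are the dominant impact transients, toe offs the smaller
  transient in a physiological window before each heel strike;
* TUG five-phase segmentation from thorax angular velocity (pitch lobe for
  sit-to-stand, yaw lobes for the turns) anchored with the first foot
  transient after each transition;
* sit-to-stand cycles from the paired convex lobes of thigh angular velocity.

Thresholds are adaptive (median + k*MAD, relative lobe fractions), so event
*times* are invariant to positive rescaling of the input and equivariant to
time shifts.  All times are in seconds from trial start; sample indices are
0-based; intervals are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class SegmentationParams:
    """Detector tuning; defaults are scale-free and documented in docs/methods.md."""

    mad_k: float = 3.0  # candidate threshold = median + k * MAD
    stride_prior_s: float = 1.1  # prior stride time; min HS spacing = 0.4x
    min_hs_spacing_frac: float = 0.4
    to_window_s: Tuple[float, float] = (0.1, 0.6)  # TO search before each HS
    onset_frac: float = 0.10  # lobe onset/offset at 10 % of peak
    lobe_height_frac: float = 0.5  # lobe peaks >= 50 % of the tallest
    lobe_min_width_s: float = 0.25  # lobes are slow; rejects noise spikes
    hs_height_frac: float = 0.5  # HS = candidates >= this fraction of the tallest
    to_min_frac: float = 0.10  # a TO peak must reach this fraction of its HS
    boundary_margin_s: float = 0.15  # lookback when anchoring on foot events


@dataclass
class GaitEvents:
    """Per-foot heel-strike and toe-off times (s), strictly increasing."""

    hs: Dict[str, np.ndarray]
    to: Dict[str, np.ndarray]
    warning: bool = False
    diagnostics: List[str] = field(default_factory=list)
    params: Dict[str, float] = field(default_factory=dict)

    def n_steps(self) -> int:
        return int(sum(len(v) for v in self.hs.values()))


@dataclass
class TugEvents:
    """Six boundaries t1..t6 delimiting the five TUG phases."""

    t: np.ndarray  # shape (6,)
    valid: bool = True
    diagnostics: List[str] = field(default_factory=list)
    params: Dict[str, float] = field(default_factory=dict)

    @property
    def total_time(self) -> float:
        return float(self.t[5] - self.t[0])

    @property
    def phase_durations(self) -> np.ndarray:
        return np.diff(self.t)


@dataclass
class StsCycles:
    """Sit-stand-sit cycles as (start, sit->stand end, stand->sit start, end)."""

    cycles: np.ndarray  # shape (n, 4)
    warning: bool = False
    mismatch: bool = False
    diagnostics: List[str] = field(default_factory=list)
    params: Dict[str, float] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return int(self.cycles.shape[0])

    @property
    def durations(self) -> np.ndarray:
        return self.cycles[:, 3] - self.cycles[:, 0]


# --------------------------------------------------------------------------
# peak machinery
# --------------------------------------------------------------------------


def _candidate_peaks(x: np.ndarray, fs: float, p: SegmentationParams,
                     min_dist_s: float) -> Tuple[np.ndarray, np.ndarray]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    height = med + p.mad_k * mad
    dist = max(1, int(round(min_dist_s * fs)))
    idx, props = signal.find_peaks(x, height=height, distance=dist)
    return idx, props.get("peak_heights", np.empty(0))


def _detect_foot_events(x: np.ndarray, fs: float, p: SegmentationParams,
                        stride_prior_s: float
                        ) -> Tuple[np.ndarray, np.ndarray, bool]:
    """HS/TO indices for one foot's resultant-acceleration series.

    Heel strikes are candidate peaks reaching ``hs_height_frac`` of the
    tallest candidate; the toe off of each heel strike is the highest minor
    peak in the physiological window before it that reaches ``to_min_frac``
    of the heel-strike height (keeps filter ringing out).  All thresholds are
    relative, so event times are invariant to positive rescaling.
    """
    x = np.asarray(x, dtype=float)
    min_dist = p.min_hs_spacing_frac * stride_prior_s
    idx, heights = _candidate_peaks(x, fs, p, min_dist)
    if idx.size == 0:
        return np.empty(0, int), np.empty(0, int), True
    hs_mask = heights >= p.hs_height_frac * heights.max()
    hs_idx = idx[hs_mask]
    hs_set = set(hs_idx.tolist())
    # the toe-off window scales with the local stride so slow gait (long
    # swing) stays covered; the prior is the fallback for isolated strikes
    strides = np.diff(hs_idx) / fs if hs_idx.size >= 2 else np.empty(0)
    default_stride = float(np.median(strides)) if strides.size else stride_prior_s
    to_idx = []
    w_lo_frac, w_hi_frac = p.to_window_s
    for k, h in enumerate(hs_idx):
        local = []
        if k > 0:
            local.append(strides[k - 1])
        if k < strides.size:
            local.append(strides[k])
        stride_local = float(np.median(local)) if local else default_stride
        upper_s = max(w_hi_frac, 0.55 * stride_local)
        lo = max(0, h - int(round(upper_s * fs)))
        hi = max(lo + 1, h - int(round(w_lo_frac * fs)))
        seg = x[lo:hi]
        cand, _ = signal.find_peaks(seg, height=p.to_min_frac * x[h])
        cand = np.asarray([c for c in cand if (c + lo) not in hs_set], dtype=int)
        if cand.size:
            to_idx.append(lo + int(cand[np.argmax(seg[cand])]))
    return hs_idx, np.asarray(sorted(to_idx), dtype=int), False


FootSeries = Union[np.ndarray, Mapping[str, np.ndarray]]


def detect_gait_events(shank_resultant: FootSeries, fs_hz: float,
                       cadence_prior_spm: Optional[float] = None,
                       params: Optional[SegmentationParams] = None
                       ) -> GaitEvents:
    """Heel-strike / toe-off detection from resultant shank acceleration.

    ``shank_resultant`` is either one low-passed resultant series (treated as
    foot "L") or a mapping of foot label -> series.  A cadence prior
    (steps/min) tightens the minimum heel-strike spacing; without one the
    default stride prior applies.  An input with no usable peaks yields empty
    event lists with the warning flag set, never an exception.
    """
    p = params or SegmentationParams()
    stride_prior = (120.0 / cadence_prior_spm if cadence_prior_spm
                    else p.stride_prior_s)
    series = ({"L": np.asarray(shank_resultant)}
              if isinstance(shank_resultant, np.ndarray)
              else {k: np.asarray(v) for k, v in shank_resultant.items()})
    hs, to, diags = {}, {}, []
    warning = False
    for foot, x in series.items():
        hs_i, to_i, empty = _detect_foot_events(x, fs_hz, p, stride_prior)
        if empty:
            warning = True
            diags.append(f"foot {foot}: no peaks above adaptive threshold")
        hs[foot] = hs_i / fs_hz
        to[foot] = to_i / fs_hz
        # alternation check: each HS should be preceded by a TO closer than
        # the previous HS (TO < HS < TO ...)
        for k in range(min(len(hs[foot]), len(to[foot]))):
            if to[foot][k] >= hs[foot][k]:
                warning = True
                diags.append(f"foot {foot}: TO/HS alternation violated at #{k}")
                break
    return GaitEvents(hs=hs, to=to, warning=warning, diagnostics=diags,
                      params={"stride_prior_s": stride_prior, "mad_k": p.mad_k,
                              "hs_height_frac": p.hs_height_frac})


def count_steps(events: GaitEvents) -> int:
    """Total number of heel strikes across both feet."""
    return events.n_steps()


# --------------------------------------------------------------------------
# lobes
# --------------------------------------------------------------------------


def _lobe_peaks(a: np.ndarray, fs: float, p: SegmentationParams,
                min_dist_s: float) -> np.ndarray:
    """Peaks of slow high-amplitude lobes on a rectified series.

    Height is relative (scale-invariant); the width requirement at half
    height separates genuine movement lobes from sensor-noise spikes, so a
    flat or noise-only input yields no lobes.
    """
    amax = float(a.max(initial=0.0))
    if amax <= 0:
        return np.empty(0, int)
    idx, _ = signal.find_peaks(
        a,
        height=p.lobe_height_frac * amax,
        distance=max(1, int(round(min_dist_s * fs))),
        width=max(1.0, p.lobe_min_width_s * fs),
        rel_height=0.5,
    )
    return idx


def _onset_offset(a: np.ndarray, peak: int, frac: float) -> Tuple[float, float]:
    """Fractional indices where ``a`` crosses ``frac`` of the peak value.

    The integer bracket is refined by linear interpolation between the two
    samples straddling the threshold, removing the half-sample quantization
    of onset/offset (and hence duration) estimates.
    """
    thr = frac * a[peak]
    lo = peak
    while lo > 0 and a[lo - 1] >= thr:
        lo -= 1
    hi = peak
    n = a.shape[0]
    while hi < n - 1 and a[hi + 1] >= thr:
        hi += 1
    lo_f, hi_f = float(lo), float(hi)
    if lo > 0 and a[lo] > a[lo - 1]:
        lo_f = lo - (a[lo] - thr) / (a[lo] - a[lo - 1])
    if hi < n - 1 and a[hi] > a[hi + 1]:
        hi_f = hi + (a[hi] - thr) / (a[hi] - a[hi + 1])
    return lo_f, hi_f


def segment_tug(thorax_angvel: np.ndarray,
                feet_acc_resultant: Mapping[str, np.ndarray],
                fs_hz: float,
                params: Optional[SegmentationParams] = None) -> TugEvents:
    """Five-phase TUG segmentation.

    t1 = onset of the first thorax pitch lobe (sit-to-stand start);
    t3, t5 = onsets of the two thorax yaw lobes (turns); t6 = offset of the
    last pitch lobe (seated again); t2 and t4 = first foot transient after
    the preceding transition ends.  If any anchor is missing the result is
    returned with ``valid=False`` and diagnostics naming the boundary.
    """
    p = params or SegmentationParams()
    w = np.asarray(thorax_angvel, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3:
        raise ValueError("thorax_angvel must be (n, 3)")
    pitch = np.abs(w[:, 1])
    yaw = np.abs(w[:, 2])
    diags: List[str] = []
    t = np.full(6, np.nan)

    pitch_peaks = _lobe_peaks(pitch, fs_hz, p, min_dist_s=1.0)
    yaw_peaks = _lobe_peaks(yaw, fs_hz, p, min_dist_s=1.0)
    if pitch_peaks.size < 1:
        diags.append("t1: no thorax pitch lobe found")
    if yaw_peaks.size < 2:
        diags.append("t3/t5: fewer than two thorax yaw lobes found")

    s2s_end_i = None
    if pitch_peaks.size:
        lo, hi = _onset_offset(pitch, int(pitch_peaks[0]), p.onset_frac)
        t[0] = lo / fs_hz
        s2s_end_i = hi
    turn_end_i = None
    if yaw_peaks.size >= 2:
        lo1, hi1 = _onset_offset(yaw, int(yaw_peaks[0]), p.onset_frac)
        t[2] = lo1 / fs_hz
        turn_end_i = hi1
        lo2, _ = _onset_offset(yaw, int(yaw_peaks[1]), p.onset_frac)
        t[4] = lo2 / fs_hz
    if pitch_peaks.size:
        last = int(pitch_peaks[-1])
        if pitch_peaks.size < 2 or (not np.isnan(t[4]) and last / fs_hz < t[4]):
            diags.append("t6: no sit-down pitch lobe after the second turn")
        else:
            _, hi = _onset_offset(pitch, last, p.onset_frac)
            t[5] = hi / fs_hz

    # foot transients (heel strikes) for walk-phase anchors
    foot_hs: List[float] = []
    for foot, series in feet_acc_resultant.items():
        hs_i, _, _ = _detect_foot_events(np.asarray(series, float), fs_hz, p,
                                         p.stride_prior_s)
        foot_hs.extend((hs_i / fs_hz).tolist())
    foot_hs_arr = np.sort(np.asarray(foot_hs))

    def first_hs_after(t0: float, label: str) -> float:
        later = foot_hs_arr[foot_hs_arr >= t0 - p.boundary_margin_s]
        if later.size == 0:
            diags.append(f"{label}: no foot transient after {t0:.2f} s")
            return np.nan
        return float(later[0])

    if s2s_end_i is not None:
        t[1] = first_hs_after(s2s_end_i / fs_hz, "t2")
    else:
        diags.append("t2: unavailable (sit-to-stand lobe missing)")
    if turn_end_i is not None:
        t[3] = first_hs_after(turn_end_i / fs_hz, "t4")
    else:
        diags.append("t4: unavailable (turn lobe missing)")

    valid = bool(np.all(np.isfinite(t)) and np.all(np.diff(t) > 0))
    if not valid and not diags:
        diags.append("boundary ordering could not be established")
    return TugEvents(t=t, valid=valid, diagnostics=diags,
                     params={"onset_frac": p.onset_frac, "mad_k": p.mad_k})


def detect_sts_cycles(thigh_angvel: np.ndarray, fs_hz: float,
                      expected_cycles: Optional[int] = None,
                      params: Optional[SegmentationParams] = None) -> StsCycles:
    """Sit-stand-sit cycle detection from a thigh angular-velocity series.

    Convex lobes (rise and descent) are located on the rectified signal; their
    10 %-of-peak crossings give the sub-phase boundaries, and consecutive lobe
    pairs form cycles.  A flat input yields zero cycles with the warning flag;
    a count disagreeing with ``expected_cycles`` sets the mismatch flag (no
    silent correction).
    """
    p = params or SegmentationParams()
    x = np.asarray(thigh_angvel, dtype=float)
    if x.ndim == 2:
        x = x[:, 1]  # pitch channel
    a = np.abs(x)
    diags: List[str] = []
    peaks = _lobe_peaks(a, fs_hz, p, min_dist_s=0.5)
    if peaks.size == 0:
        return StsCycles(cycles=np.empty((0, 4)), warning=True,
                         mismatch=expected_cycles not in (None, 0),
                         diagnostics=["no angular-velocity lobes found"])
    bounds = [_onset_offset(a, int(pk), p.onset_frac) for pk in peaks]
    # merge lobes that share a boundary (should not occur on nominal input)
    merged: List[Tuple[int, int]] = []
    for lo, hi in bounds:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    odd = len(merged) % 2 == 1
    if odd:
        diags.append(f"odd lobe count ({len(merged)}); last lobe unpaired")
    pairs = [(merged[i], merged[i + 1]) for i in range(0, len(merged) - 1, 2)]
    cycles = np.asarray(
        [(lo1 / fs_hz, hi1 / fs_hz, lo2 / fs_hz, hi2 / fs_hz)
         for (lo1, hi1), (lo2, hi2) in pairs]
    ).reshape(-1, 4)
    mismatch = expected_cycles is not None and cycles.shape[0] != expected_cycles
    if mismatch:
        diags.append(
            f"detected {cycles.shape[0]} cycles, expected {expected_cycles}"
        )
    return StsCycles(cycles=cycles, warning=odd, mismatch=mismatch,
                     diagnostics=diags,
                     params={"onset_frac": p.onset_frac,
                             "lobe_height_frac": p.lobe_height_frac})
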