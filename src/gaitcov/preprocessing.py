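"""Marker-trajectory preprocessing: zero-phase low-pass filtering, heel-strike
detection, and extraction of back-foot-normalized step postures.

Step postures are whole-body joint-angle vectors sampled at heel-strike
frames.  Postures at frames with any missing required marker are incomplete
and discarded; of the remaining, only the last ``max_postures`` (default 20)
per foot and trial enter the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

SIDES = ("left", "right")


@dataclass
class TrajectorySet:
    """Labeled 3D marker trajectories at a fixed sampling rate.

    ``data[label]`` has shape (n_frames, 3) in metres; ``valid[label]`` is a
    per-frame boolean mask (False where the marker is missing/NaN).
    """

    data: dict[str, np.ndarray]
    rate_hz: float
    valid: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        n = None
        for label, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {label}: expected shape (n, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all trajectories must have the same frame count")
            self.data[label] = arr
        self.n_frames = 0 if n is None else n
        for label, arr in self.data.items():
            mask = self.valid.get(label)
            finite = np.all(np.isfinite(arr), axis=1)
            if mask is None:
                mask = finite
            else:
                mask = np.asarray(mask, bool) & finite
            self.valid[label] = mask

    @property
    def labels(self) -> list[str]:
        return list(self.data)

    def frame_markers(self, frame: int) -> dict[str, np.ndarray]:
        """Valid markers at one frame, label -> 3D point."""
        return {
            label: self.data[label][frame]
            for label in self.data
            if self.valid[label][frame]
        }


@dataclass
class GaitEvents:
    """Ordered heel strikes as (frame index, side) pairs.

    Frames are strictly increasing; non-alternating sides are logged as a
    warning but kept (they occur with missed detections in valid gait data).
    """

    events: list[tuple[int, str]]

    def __post_init__(self):
        frames = [f for f, _ in self.events]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("event frames must be strictly increasing")
        for _, side in self.events:
            if side not in SIDES:
                raise ValueError(f"invalid side {side!r}")
        sides = [s for _, s in self.events]
        n_rep = sum(a == b for a, b in zip(sides, sides[1:]))
        if n_rep and len(set(sides)) > 1:
            logger.warning("gait events: %d non-alternating side pairs", n_rep)

    def frames(self, side: str | None = None) -> list[int]:
        return [f for f, s in self.events if side is None or s == side]

    def __len__(self) -> int:
        return len(self.events)

    @staticmethod
    def merge(*event_sets: "GaitEvents") -> "GaitEvents":
        allev = sorted(ev for es in event_sets for ev in es.events)
        return GaitEvents(allev)


def _filtfilt_lowpass(x: np.ndarray, cutoff_hz: float, rate_hz: float, order: int) -> np.ndarray:
    b, a = signal.butter(order, cutoff_hz / (rate_hz / 2.0), btype="low")
    # reflective padding of 3 filter lengths keeps endpoint transients out of
    # the first/last heel strikes
    padlen = 3 * max(len(a), len(b))
    return signal.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def lowpass_filter(
    traj: TrajectorySet, cutoff_hz: float = 10.0, order: int = 3
) -> TrajectorySet:
    """Bidirectional (zero-phase) Butterworth low-pass filter of all markers.

    Forward-backward filtering squares the single-pass magnitude response, so
    the effective gain at the cutoff is 1/2.  Each marker's contiguous valid
    runs are filtered independently; runs shorter than the padding length are
    invalidated rather than filtered.
    """
    nyquist = traj.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    min_len = 3 * (order + 1) + 1
    if traj.n_frames <= min_len:
        raise ValueError(
            f"trajectory too short to filter ({traj.n_frames} <= {min_len} frames)"
        )
    out_data: dict[str, np.ndarray] = {}
    out_valid: dict[str, np.ndarray] = {}
    for label, arr in traj.data.items():
        mask = traj.valid[label].copy()
        out = np.full_like(arr, np.nan)
        # contiguous valid runs
        padded = np.concatenate([[False], mask, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        stops = np.flatnonzero(~padded[1:] & padded[:-1])
        for s, e in zip(starts, stops):
            if e - s > min_len:
                out[s:e] = _filtfilt_lowpass(arr[s:e], cutoff_hz, traj.rate_hz, order)
            else:
                mask[s:e] = False
        out_data[label] = out
        out_valid[label] = mask
    return TrajectorySet(out_data, traj.rate_hz, out_valid)


def _dominant_period_frames(x: np.ndarray, rate_hz: float) -> float:
    """Dominant periodicity of a signal, in frames; raises if none detectable."""
    x = x - np.mean(x)
    if np.std(x) < 1e-4:  # < 0.1 mm of motion: not walking
        raise ValueError("no gait periodicity: signal is flat")
    freqs, power = signal.periodogram(x, fs=rate_hz)
    band = (freqs > 0.2) & (freqs < 3.0)
    if not np.any(band):
        raise ValueError("signal too short to resolve gait periodicity")
    peak = np.argmax(power[band])
    peak_power = power[band][peak]
    if peak_power < 20.0 * np.median(power[band]):
        raise ValueError("no dominant periodicity in the stride band (0.2-3 Hz)")
    f0 = freqs[band][peak]
    return rate_hz / f0


def _refine_peak(x: np.ndarray, peak: int, half_window: int) -> int:
    """Quadratic (parabolic) vertex refinement of a local maximum, rounded to
    the nearest frame.  Averages measurement noise over the fit window."""
    lo = max(0, peak - half_window)
    hi = min(len(x), peak + half_window + 1)
    t = np.arange(lo, hi, dtype=float)
    coeffs = np.polyfit(t - peak, x[lo:hi], 2)
    if coeffs[0] >= 0:  # not concave; keep the raw argmax
        return peak
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    if abs(vertex) > half_window:
        return peak
    return int(round(peak + vertex))


def detect_heel_strikes(
    traj: TrajectorySet,
    side: str,
    heel_marker: str | None = None,
    pelvis_markers: Sequence[str] = ("LASI", "RASI", "LPSI", "RPSI"),
) -> GaitEvents:
    """Coordinate-based treadmill heel-strike detection for one side.

    Heel strikes are local maxima of the heel marker's fore-aft position
    relative to the pelvis (anterior-extreme method), with a minimum
    inter-event separation of 0.4 stride periods and parabolic refinement of
    each peak over +-0.08 s.
    """
    if side not in SIDES:
        raise ValueError(f"invalid side {side!r}")
    if heel_marker is None:
        heel_marker = ("L" if side == "left" else "R") + "HEE"
    if heel_marker not in traj.data:
        raise ValueError(f"heel marker {heel_marker} not in trajectory set")
    pelvis = [m for m in pelvis_markers if m in traj.data]
    if not pelvis:
        raise ValueError("no pelvis markers available for heel-strike detection")
    heel_x = traj.data[heel_marker][:, 0]
    pelvis_x = np.mean([traj.data[m][:, 0] for m in pelvis], axis=0)
    x = heel_x - pelvis_x
    if not np.all(np.isfinite(x)):
        # detection tolerates gaps by linear interpolation; completeness is
        # enforced later at the posture level
        ok = np.isfinite(x)
        if ok.sum() < 2:
            raise ValueError("heel/pelvis signal entirely invalid")
        x = np.interp(np.arange(len(x)), np.flatnonzero(ok), x[ok])

    period = _dominant_period_frames(x, traj.rate_hz)
    distance = max(1, int(round(0.4 * period)))
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=0.25 * np.ptp(x))
    half_window = max(2, int(round(0.08 * traj.rate_hz)))
    refined = sorted({_refine_peak(x, p, half_window) for p in peaks})
    return GaitEvents([(int(f), side) for f in refined])


@dataclass
class StepPosture:
    theta: np.ndarray
    front_side: str
    frame: int
    complete: bool
    back_mtp: np.ndarray | None = None


@dataclass
class StepPostureEnsemble:
    """n x d joint-angle matrix for one (trial, side) after selection.

    ``root_rot`` is the fixed per-ensemble pelvis-orientation context used
    when the forward model is evaluated for this ensemble.
    """

    angles: np.ndarray
    front_side: str
    frames: list[int]
    meta: dict = field(default_factory=dict)
    root_rot: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be an (n, d) matrix")
        if self.front_side not in SIDES:
            raise ValueError(f"invalid side {self.front_side!r}")

    @property
    def n(self) -> int:
        return self.angles.shape[0]

    @property
    def d(self) -> int:
        return self.angles.shape[1]

    @property
    def mean_posture(self) -> np.ndarray:
        return self.angles.mean(axis=0)


def extract_step_postures(
    postures: Sequence[StepPosture],
    side: str,
    max_postures: int = 20,
    meta: Mapping | None = None,
    root_rot: np.ndarray | None = None,
) -> StepPostureEnsemble:
    """Apply the completeness and last-``max_postures`` selection rule.

    Incomplete postures are discarded; of the complete ones, the *last*
    ``max_postures`` are kept in temporal order.  Fewer than 2 complete
    postures make the step-to-step covariance undefined and are rejected;
    2-19 are accepted with a logged warning.
    """
    if max_postures < 1:
        raise ValueError("max_postures must be >= 1")
    rows = [p for p in postures if p.front_side == side]
    if any(b.frame <= a.frame for a, b in zip(rows, rows[1:])):
        raise ValueError("postures must be in increasing frame order")
    complete = [p for p in rows if p.complete]
    kept = complete[-max_postures:]
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} complete step postures on side {side}; "
            "need >= 2 for covariance estimation"
        )
    if len(kept) < max_postures:
        logger.warning(
            "side %s: only %d complete step postures (requested %d)",
            side, len(kept), max_postures,
        )
    return StepPostureEnsemble(
        angles=np.vstack([p.theta for p in kept]),
        front_side=side,
        frames=[p.frame for p in kept],
        meta=dict(meta or {}),
        root_rot=root_rot,
    )
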