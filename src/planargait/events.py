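"""Gait-cycle segmentation and stance-foot detection.

A gait cycle is delimited by the mid-swing event: the instant the observed
limb's ankle centre passes directly under the hip centre in the sagittal
plane while swinging forward.  In forward coordinates that is a negative ->
positive zero crossing of ``d(t) = x_ankle - x_hip`` gated by the ankle's
forward velocity (the stance-phase reverse crossing, where the hip passes
over the stationary ankle, is excluded both by the crossing direction and
by the velocity gate).  Event times are refined to sub-frame resolution by
linear interpolation of ``d`` between the bracketing frames.

Foot placements (needed for spatial parameters) are maximal runs of frames
whose ankle forward speed stays below a stance threshold; the placement
position is the median ankle x over the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DirectionError, EventDetectionError, ValidationError
from .kinematics import JointAngleSeries
from .pose import PoseSequence

__all__ = [
    "GaitCycle",
    "FootPlacement",
    "NormalizedCurve",
    "detect_cycles",
    "detect_foot_placements",
    "normalize_cycle",
    "ensemble_stats",
]


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle of one limb, delimited by sub-frame event times."""

    t_start: float
    t_end: float
    side: str
    frame_span: tuple[int, int]  # inclusive frame-index range inside cycle
    valid: bool = True

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start):
            raise ValidationError("cycle must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FootPlacement:
    """A stance foot position: median ankle x over one low-speed run."""

    t: float
    x_mm: float
    side: str


def _forward_sign(hip_x: np.ndarray, min_disp_mm: float = 100.0) -> float:
    ok = np.isfinite(hip_x)
    if ok.sum() < 2:
        raise DirectionError("too few hip samples to infer direction")
    net = hip_x[ok][-1] - hip_x[ok][0]
    if abs(net) < min_disp_mm:
        raise DirectionError(
            f"net hip displacement {net:.0f} mm < {min_disp_mm} mm; "
            "walking direction ambiguous")
    return 1.0 if net > 0 else -1.0


def _smooth_velocity(x: np.ndarray, fps: float, window_s: float = 0.25) -> np.ndarray:
    """Forward velocity via a Savitzky-Golay derivative (noise-robust).

    NaN gaps are linearly bridged before filtering and restored after; the
    window is clipped to the series length.
    """
    n = len(x)
    w = int(round(window_s * fps))
    w = max(5, w | 1)  # odd, >= 5
    if w >= n:
        w = n - 1 if (n - 1) % 2 == 1 else n - 2
    if w < 3:
        return np.gradient(x, 1.0 / fps)
    nan = ~np.isfinite(x)
    xi = x.copy()
    if nan.any() and (~nan).any():
        idx = np.arange(n)
        xi[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    v = savgol_filter(xi, w, polyorder=2, deriv=1, delta=1.0 / fps)
    v[nan] = np.nan
    return v


def detect_cycles(
    world_seq: PoseSequence,
    side: str,
    v_min: float | None = None,
    v_min_fraction: float = 0.2,
    invalid_fill_fraction: float = 0.2,
) -> list[GaitCycle]:
    """Segment a straight walking pass into gait cycles for one limb.

    ``v_min`` is the swing gate: crossings where the ankle's forward
    velocity is below it are rejected.  By default it is
    ``v_min_fraction`` x the mean hip forward speed over the pass.  Cycles
    in which more than ``invalid_fill_fraction`` of the required-node
    samples were gap-filled are flagged invalid.
    """
    if world_seq.space != "world_mm":
        raise EventDetectionError("detect_cycles expects a world_mm sequence")
    hip = world_seq.node_xy(f"{side}_hip")[:, 0]
    ankle = world_seq.node_xy(f"{side}_ankle")[:, 0]
    t = world_seq.t
    sgn = _forward_sign(hip)
    hip = sgn * hip
    ankle = sgn * ankle

    ok = np.isfinite(hip)
    duration = t[ok][-1] - t[ok][0]
    mean_hip_speed = (hip[ok][-1] - hip[ok][0]) / duration
    if v_min is None:
        v_min = v_min_fraction * mean_hip_speed

    d = ankle - hip
    v_ankle = _smooth_velocity(ankle, world_seq.fps)

    events: list[float] = []
    for i in range(len(d) - 1):
        if not (np.isfinite(d[i]) and np.isfinite(d[i + 1])):
            continue
        if d[i] < 0 <= d[i + 1]:
            frac = -d[i] / (d[i + 1] - d[i])
            tc = t[i] + frac * (t[i + 1] - t[i])
            vc = v_ankle[i] + frac * (v_ankle[i + 1] - v_ankle[i])
            if np.isfinite(vc) and vc > v_min:
                events.append(float(tc))
    if len(events) < 2:
        raise EventDetectionError(
            f"only {len(events)} swing crossing(s) found for {side} limb")

    # gap-fill bookkeeping for the quality flag
    req = world_seq.schema.indices(
        [f"{side}_{p}" for p in ("shoulder", "hip", "knee", "ankle")])
    filled_any = world_seq.filled[:, req].any(axis=1)

    cycles = []
    for t0, t1 in zip(events[:-1], events[1:]):
        span = np.flatnonzero((t >= t0) & (t <= t1))
        frame_span = (int(span[0]), int(span[-1])) if span.size else (0, -1)
        frac_filled = float(filled_any[span].mean()) if span.size else 1.0
        cycles.append(GaitCycle(t0, t1, side, frame_span,
                                valid=frac_filled <= invalid_fill_fraction))
    return cycles


def detect_foot_placements(
    world_seq: PoseSequence,
    side: str,
    v_stance: float = 100.0,
    min_duration_s: float = 0.1,
) -> list[FootPlacement]:
    """Foot placements as maximal low-forward-speed ankle runs.

    A run qualifies when the ankle forward speed stays below ``v_stance``
    (mm/s) for at least ``min_duration_s``.  Placement x is the median
    ankle x over the run; t is the run midpoint.
    """
    ankle = world_seq.node_xy(f"{side}_ankle")[:, 0]
    t = world_seq.t
    v = _smooth_velocity(ankle, world_seq.fps)
    slow = np.isfinite(v) & (np.abs(v) < v_stance)
    placements = []
    i, n = 0, len(slow)
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j < n and slow[j]:
            j += 1
        if t[j - 1] - t[i] >= min_duration_s:
            xs = ankle[i:j]
            placements.append(FootPlacement(
                t=float(0.5 * (t[i] + t[j - 1])),
                x_mm=float(np.nanmedian(xs)),
                side=side,
            ))
        i = j
    if not placements:
        raise EventDetectionError(f"no stance run found for {side} ankle")
    return placements


@dataclass
class NormalizedCurve:
    """An angle curve resampled onto an equal-phase [0, 100]% grid."""

    phase: np.ndarray  # percent of gait cycle
    values: np.ndarray
    valid: bool = True


def normalize_cycle(
    angles: JointAngleSeries,
    cycle: GaitCycle,
    joint: str = "hip",
    n_points: int = 101,
    max_missing_fraction: float = 0.2,
) -> NormalizedCurve:
    """Resample one joint's angle curve onto ``n_points`` equal phases.

    Phase 0 is the cycle-start event (ankle under hip), 100% the next one.
    Linear interpolation in time; if more than ``max_missing_fraction`` of
    in-cycle samples are missing the curve's quality flag is set false.
    """
    y = {"hip": angles.hip_deg, "knee": angles.knee_deg}[joint]
    t = angles.t
    if cycle.t_start < t[0] - 1e-9 or cycle.t_end > t[-1] + 1e-9:
        raise ValidationError("cycle lies outside the angle series time span")
    in_cycle = (t >= cycle.t_start) & (t <= cycle.t_end)
    n_in = int(in_cycle.sum())
    missing_frac = float(np.mean(~np.isfinite(y[in_cycle]))) if n_in else 1.0
    ok = np.isfinite(y)
    grid_t = np.linspace(cycle.t_start, cycle.t_end, n_points)
    values = np.interp(grid_t, t[ok], y[ok])
    return NormalizedCurve(
        phase=np.linspace(0.0, 100.0, n_points),
        values=values,
        valid=missing_frac <= max_missing_fraction,
    )


def ensemble_stats(curves: list[NormalizedCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD over normalized curves.

    SD uses ddof=1 and is reported as 0 for a single curve.
    """
    if not curves:
        raise ValidationError("ensemble_stats needs at least one curve")
    lengths = {len(c.values) for c in curves}
    if len(lengths) != 1:
        raise ValidationError(f"curve length mismatch: {sorted(lengths)}")
    mat = np.vstack([c.values for c in curves])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return mean, sd
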