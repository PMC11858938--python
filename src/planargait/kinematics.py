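"""Sagittal hip and knee angles from world-space keypoints.

Angle conventions (flexion positive, degrees, range (-180, 180]):

* hip — signed angle from the downward prolongation of the trunk vector
  (shoulder -> hip) to the thigh vector (hip -> knee); positive when the
  knee is forward of the trunk line.  The trunk (not an absolute vertical)
  is the reference because the measured system has no pelvis landmarks; a
  ``reference="vertical"`` switch is provided for sensitivity analysis.
* knee — signed angle from the prolongation of the thigh vector (hip ->
  knee) to the shank vector (knee -> ankle); 0 at full extension, positive
  flexion (ankle behind the thigh line), negative hyperextension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InsufficientDataError
from .pose import PoseSequence

__all__ = ["JointAngleSeries", "hip_angle", "knee_angle", "angle_series"]

_EPS = 1e-12


@dataclass
class JointAngleSeries:
    """Per-frame hip/knee sagittal angles for one limb (NaN where missing)."""

    t: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hip_deg = np.asarray(self.hip_deg, dtype=float)
        self.knee_deg = np.asarray(self.knee_deg, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


def _signed_angle(ref: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Signed angle (deg) rotating ``ref`` onto ``vec``.

    Positive when ``vec`` points forward (+x) of the reference line, for
    reference vectors that point generally downward; implemented as the
    atan2 of the 2D cross and dot products, which is what makes the sign
    purely geometric and frame-rotation invariant.
    """
    cross = ref[..., 0] * vec[..., 1] - ref[..., 1] * vec[..., 0]
    dot = ref[..., 0] * vec[..., 0] + ref[..., 1] * vec[..., 1]
    return np.degrees(np.arctan2(cross, dot))


def hip_angle(shoulder, hip, knee, reference: str = "trunk") -> float:
    """Signed sagittal hip angle from three world points (degrees).

    Flexion (knee forward of the trunk line) is positive.  With
    ``reference="vertical"`` the trunk vector is replaced by a fixed
    downward vertical.
    """
    shoulder = np.asarray(shoulder, dtype=float)
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    if reference == "trunk":
        down = hip - shoulder  # downward prolongation of shoulder->hip
    elif reference == "vertical":
        down = np.broadcast_to(np.array([0.0, -1.0]), hip.shape).copy()
    else:
        raise ValueError(f"unknown hip reference {reference!r}")
    thigh = knee - hip
    if (np.linalg.norm(down, axis=-1).min() if down.ndim > 1
            else np.linalg.norm(down)) < _EPS:
        raise GeometryError("coincident shoulder and hip")
    if (np.linalg.norm(thigh, axis=-1).min() if thigh.ndim > 1
            else np.linalg.norm(thigh)) < _EPS:
        raise GeometryError("coincident hip and knee")
    # with +x forward and +y up, rotating the downward trunk line toward +x
    # (knee forward = flexion) gives a positive atan2 angle directly
    return _signed_angle(down, thigh)


def knee_angle(hip, knee, ankle) -> float:
    """Signed sagittal knee angle from three world points (degrees).

    0 at full extension (collinear), positive flexion (ankle behind the
    thigh prolongation), negative hyperextension.
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    thigh = knee - hip
    shank = ankle - knee
    if (np.linalg.norm(thigh, axis=-1).min() if thigh.ndim > 1
            else np.linalg.norm(thigh)) < _EPS:
        raise GeometryError("coincident hip and knee")
    if (np.linalg.norm(shank, axis=-1).min() if shank.ndim > 1
            else np.linalg.norm(shank)) < _EPS:
        raise GeometryError("coincident knee and ankle")
    # flexion = shank rotated backward (toward -x) from the thigh
    # prolongation, which is a negative atan2 rotation in this frame
    return -_signed_angle(thigh, shank)


def angle_series(
    seq: PoseSequence,
    side: str,
    reference: str = "trunk",
    smooth_window: int | None = None,
    forward: float | None = None,
) -> JointAngleSeries:
    """Per-frame hip/knee angles for one limb.

    Frames with any required node missing yield NaN angles.  Optional
    moving-average smoothing (odd ``smooth_window``; default none).

    ``forward`` fixes the walking direction sign (+1 = +x); by default it is
    inferred from the net hip displacement, so flexion stays positive for a
    subject walking in -x (mirror symmetry).
    """
    if seq.space != "world_mm":
        raise GeometryError("angle_series expects a world_mm sequence")
    if side not in ("left", "right"):
        raise ValueError(f"side must be left/right, got {side!r}")
    sh = seq.node_xy(f"{side}_shoulder")
    hp = seq.node_xy(f"{side}_hip")
    kn = seq.node_xy(f"{side}_knee")
    ak = seq.node_xy(f"{side}_ankle")
    valid = np.isfinite(np.concatenate([sh, hp, kn, ak], axis=1)).all(axis=1)
    if valid.sum() < 2:
        raise InsufficientDataError(
            f"fewer than 2 frames with all {side} nodes present")
    if forward is None:
        hx = hp[valid, 0]
        net = hx[-1] - hx[0]
        forward = -1.0 if net < 0 else 1.0
    sgn = float(np.sign(forward)) or 1.0
    if sgn < 0:  # mirror the x axis so +x is the walking direction
        sh, hp, kn, ak = (p * np.array([-1.0, 1.0]) for p in (sh, hp, kn, ak))
    hip_deg = np.full(seq.n_frames, np.nan)
    knee_deg = np.full(seq.n_frames, np.nan)
    hip_deg[valid] = hip_angle(sh[valid], hp[valid], kn[valid],
                               reference=reference)
    knee_deg[valid] = knee_angle(hp[valid], kn[valid], ak[valid])
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < 1:
            raise ValueError("smooth_window must be odd and positive")
        hip_deg = _nan_moving_average(hip_deg, smooth_window)
        knee_deg = _nan_moving_average(knee_deg, smooth_window)
    return JointAngleSeries(seq.t.copy(), hip_deg, knee_deg, side)


def _nan_moving_average(x: np.ndarray, w: int) -> np.ndarray:
    half = w // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        win = x[lo:hi]
        if np.isfinite(x[i]) and np.isfinite(win).any():
            out[i] = np.nanmean(win)
    return out
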