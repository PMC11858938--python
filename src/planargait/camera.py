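"""Pixel <-> world coordinate conversion for the two fixed cameras.

The side camera views the subject's sagittal plane square-on; keypoints are
back-projected with a single-plane pinhole model at depth ``Z = distance_mm
- lateral_offset_mm`` (the subject's sagittal plane), after inverting Brown
radial lens distortion.  The front camera provides a stature-derived mm/px
scale and the subject's mediolateral offset from the walkway centre, which
feeds the side camera's depth.

Conventions: image pixels have origin top-left with +u rightward and +v
downward; the world frame is +x along the walking direction and +y up, in
millimetres.  The vertical flip between the two happens here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import CalibrationError, GeometryError, NumericalError
from .pose import PoseSequence

__all__ = [
    "CameraModel",
    "WalkwayGeometry",
    "distort_points",
    "undistort_points",
    "project_to_camera",
    "side_pixels_to_world",
    "front_pixels_to_world",
    "front_scale",
    "estimate_lateral_offset",
]


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics plus mounting geometry of one fixed camera.

    ``distance_mm`` is the perpendicular distance from the optical centre to
    the walkway centre sagittal plane; ``height_mm`` the optical-centre
    height above the floor.  ``k1``/``k2`` are Brown radial distortion
    coefficients on radii normalized by ``f_px`` (dimensionless).
    """

    f_px: float = 600.0
    c: tuple[float, float] = (960.0, 540.0)
    k1: float = 0.0
    k2: float = 0.0
    distance_mm: float = 4000.0
    height_mm: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.f_px > 0):
            raise GeometryError("focal length must be positive")
        if not (self.distance_mm > 0):
            raise GeometryError("mounting distance must be positive")


@dataclass(frozen=True)
class WalkwayGeometry:
    """World origin and subject offset relative to the walkway centre plane."""

    center_plane_x0: float = 0.0
    lateral_offset_mm: float = 0.0
    projection_plane_mm: float = 1340.0


def _radial_factor(pts_c: np.ndarray, cam: CameraModel) -> np.ndarray:
    r2 = np.sum((pts_c / cam.f_px) ** 2, axis=-1, keepdims=True)
    return 1.0 + cam.k1 * r2 + cam.k2 * r2 * r2


def distort_points(pts: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Forward Brown radial model: ideal pixel coords -> distorted."""
    pts = np.asarray(pts, dtype=float)
    c = np.asarray(cam.c)
    d = pts - c
    return c + d * _radial_factor(d, cam)


def undistort_points(
    pts: np.ndarray,
    cam: CameraModel,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> np.ndarray:
    """Invert the Brown radial model by fixed-point iteration.

    Solves ``distorted = ideal * (1 + k1 r^2 + k2 r^4)`` for the ideal
    point to ``tol`` pixels.  With ``k1 = k2 = 0`` the input is returned
    unchanged (single iteration, exact).
    """
    pts = np.asarray(pts, dtype=float)
    if cam.k1 == 0.0 and cam.k2 == 0.0:
        return pts.copy()
    c = np.asarray(cam.c)
    d = pts - c
    x = d.copy()
    nan = ~np.isfinite(d).all(axis=-1)
    for _ in range(max_iter):
        x_new = d / _radial_factor(x, cam)
        err = np.nanmax(np.abs(x_new - x)[~nan]) if (~nan).any() else 0.0
        x = x_new
        if err < tol:
            return c + x
    raise NumericalError(
        f"distortion inversion did not converge to {tol} px in "
        f"{max_iter} iterations (pathological coefficients?)")


def project_to_camera(
    pts_cam: np.ndarray,
    cam: CameraModel,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pinhole projection of camera-aligned 3D points to pixels.

    ``pts_cam`` is ``(..., 3)`` with X rightward in the image, Y up relative
    to the optical centre, Z the depth along the optical axis.  Applies the
    forward Brown distortion and optional i.i.d. Gaussian pixel noise
    (deterministic under a fixed ``rng``).
    """
    pts_cam = np.asarray(pts_cam, dtype=float)
    X, Y, Z = pts_cam[..., 0], pts_cam[..., 1], pts_cam[..., 2]
    finite = np.isfinite(Z)
    if np.any(Z[finite] <= 0):
        raise GeometryError("point at or behind the camera (Z <= 0)")
    u0, v0 = cam.c
    ideal = np.stack([u0 + cam.f_px * X / Z, v0 - cam.f_px * Y / Z], axis=-1)
    out = distort_points(ideal, cam)
    if noise_px > 0:
        if rng is None:
            rng = np.random.default_rng()
        out = out + rng.normal(0.0, noise_px, size=out.shape)
    return out


def side_pixels_to_world(
    seq: PoseSequence,
    cam: CameraModel,
    walkway: WalkwayGeometry | None = None,
) -> PoseSequence:
    """Back-project side-camera pixels onto the subject's sagittal plane.

    Every node is assumed to lie in the plane at depth ``Z = distance_mm -
    lateral_offset_mm``; per-node mediolateral limb offsets are the model's
    known approximation error.  The vertical axis is flipped to +y up and
    referenced to the floor through the camera height.
    """
    if seq.space != "pixel" or seq.camera_tag != "side":
        raise GeometryError("expected a pixel-space side-camera sequence")
    walkway = walkway or WalkwayGeometry()
    Z = cam.distance_mm - walkway.lateral_offset_mm
    if Z <= 0:
        raise GeometryError(f"sagittal-plane depth Z={Z} mm is not positive")
    out = seq.copy()
    flat = out.xy.reshape(-1, 2)
    ok = np.isfinite(flat).all(axis=1)
    ideal = np.full_like(flat, np.nan)
    if ok.any():
        ideal[ok] = undistort_points(flat[ok], cam)
    u0, v0 = cam.c
    world = np.empty_like(ideal)
    world[:, 0] = (ideal[:, 0] - u0) * Z / cam.f_px - walkway.center_plane_x0
    world[:, 1] = -(ideal[:, 1] - v0) * Z / cam.f_px + cam.height_mm
    out.xy = world.reshape(out.xy.shape)
    out.space = "world_mm"
    return out


def front_scale(
    calib_seq: PoseSequence,
    stature_mm: float,
    min_span_px: float = 10.0,
) -> float:
    """mm/px scale from a standing calibration sequence.

    Uses the median distance from the head-top node to the midpoint of the
    two ankle nodes across the calibration frames.  Raises
    :class:`CalibrationError` if the span is degenerate (< ``min_span_px``).
    """
    head = calib_seq.node_xy("head")
    la = calib_seq.node_xy("left_ankle")
    ra = calib_seq.node_xy("right_ankle")
    mid = 0.5 * (la + ra)
    span = np.linalg.norm(head - mid, axis=1)
    span = span[np.isfinite(span)]
    if span.size == 0:
        raise CalibrationError("no calibration frame with head and ankles")
    s = float(np.median(span))
    if s < min_span_px:
        raise CalibrationError(f"degenerate head-ankle span {s:.1f} px")
    if not (stature_mm > 0):
        raise CalibrationError("stature must be positive")
    return stature_mm / s


def front_pixels_to_world(
    seq: PoseSequence,
    stature_mm: float,
    calib_seq: PoseSequence | None = None,
    scale_mm_px: float | None = None,
    center_px: tuple[float, float] | None = None,
) -> PoseSequence:
    """Scale front-camera pixels to world millimetres.

    The scale comes either from ``scale_mm_px`` directly or from a standing
    calibration sequence via :func:`front_scale`.  Output x is the signed
    mediolateral coordinate relative to ``center_px`` (default: the image
    centre implied by the sequence, i.e. pixel ``(0, 0)`` offset is the
    caller's responsibility), y is vertical (+up).
    """
    if seq.camera_tag != "front" or seq.space != "pixel":
        raise GeometryError("expected a pixel-space front-camera sequence")
    if scale_mm_px is None:
        if calib_seq is None:
            raise CalibrationError(
                "either scale_mm_px or a calibration sequence is required")
        scale_mm_px = front_scale(calib_seq, stature_mm)
    c = np.asarray(center_px if center_px is not None else (0.0, 0.0))
    out = seq.copy()
    out.xy = np.stack(
        [(out.xy[..., 0] - c[0]) * scale_mm_px,
         -(out.xy[..., 1] - c[1]) * scale_mm_px],
        axis=-1,
    )
    out.space = "world_mm"
    return out


def estimate_lateral_offset(front_world: PoseSequence) -> tuple[np.ndarray, float]:
    """Per-frame and median mediolateral offset of the hip midpoint.

    Returns ``(per_frame_mm, median_mm)``; the median over the trial is the
    value fed to :func:`side_pixels_to_world` through
    :class:`WalkwayGeometry`.
    """
    lh = front_world.node_xy("left_hip")
    rh = front_world.node_xy("right_hip")
    mid = 0.5 * (lh + rh)
    # fall back to whichever hip is present
    only_l = np.isfinite(lh[:, 0]) & ~np.isfinite(rh[:, 0])
    only_r = np.isfinite(rh[:, 0]) & ~np.isfinite(lh[:, 0])
    mid[only_l] = lh[only_l]
    mid[only_r] = rh[only_r]
    lateral = mid[:, 0]
    if not np.isfinite(lateral).any():
        raise GeometryError("all hip nodes missing; cannot estimate offset")
    return lateral, float(np.nanmedian(lateral))


def with_lateral_offset(
    walkway: WalkwayGeometry, offset_mm: float
) -> WalkwayGeometry:
    """Convenience: a copy of ``walkway`` with the estimated subject offset."""
    return replace(walkway, lateral_offset_mm=offset_mm)
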