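"""Ground-truthed planar walking simulator and paired-systems generator.

The walker is a sagittal-plane trunk-thigh-shank chain driven by joint-angle
templates (single-harmonic hip, raised-sine swing knee) under a
single-support stance constraint: while a leg is in stance its ankle's
forward position is pinned to the foot placement, and the hip's forward
position follows from that leg's template angles.  Consequences that the
pipeline's validation relies on:

* the stance ankle is exactly stationary in x, so detected foot placements
  sit exactly on the true placements;
* successive placements are spaced exactly half the requested stride, and
  the hip advances exactly one stride per cycle period;
* the joint-angle series measured from the generated keypoints reproduce
  the template peak values exactly.

The requested stride length and the angle template over-determine the leg
geometry, so both leg segment lengths are rescaled by a single factor that
makes the template sweep realize the requested stride (about 1.01 for the
comfortable defaults, smaller for tandem).

Styles (``comfortable``, ``max``, ``tandem``) differ only in their default
stride length, cycle time, angle-template peaks and lateral foot spacing,
anchored to published camera-system group means for the three conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .camera import CameraModel, project_to_camera
from .errors import ConfigError
from .params import GaitParameters
from .pose import SIM_SCHEMA, NodeSchema, PoseSequence

__all__ = [
    "WalkerConfig",
    "PairedSystemsConfig",
    "SimulatedWalk",
    "generate_walk",
    "generate_standing",
    "render_views",
    "generate_paired",
    "STYLE_DEFAULTS",
    "DEFAULT_SIDE_CAMERA",
    "DEFAULT_FRONT_CAMERA",
]

#: Per-style defaults: stride (mm), cycle time (s), hip/knee peak angles
#: (deg, signed), lateral spacing between the feet (mm).
STYLE_DEFAULTS = {
    "comfortable": dict(stride_length_mm=1400.0, stride_time_s=1.047,
                        hip_flex_peak_deg=30.3, hip_ext_peak_deg=-18.8,
                        knee_flex_peak_deg=65.7, knee_ext_peak_deg=2.5,
                        hip_width_mm=200.0),
    "max": dict(stride_length_mm=1617.6, stride_time_s=0.86,
                hip_flex_peak_deg=35.4, hip_ext_peak_deg=-22.6,
                knee_flex_peak_deg=65.9, knee_ext_peak_deg=3.3,
                hip_width_mm=200.0),
    "tandem": dict(stride_length_mm=670.2, stride_time_s=1.17,
                   hip_flex_peak_deg=25.2, hip_ext_peak_deg=-6.1,
                   knee_flex_peak_deg=60.8, knee_ext_peak_deg=4.9,
                   hip_width_mm=40.0),
}

# side default: the stitched wide-view equivalent — a 7200 px panorama at
# ~2 mm/px on the walkway centre plane, covering a full 10-stride pass
DEFAULT_SIDE_CAMERA = CameraModel(f_px=2000.0, c=(3600.0, 540.0),
                                  distance_mm=4000.0, height_mm=1000.0)
DEFAULT_FRONT_CAMERA = CameraModel(f_px=1200.0, c=(960.0, 540.0),
                                   distance_mm=10000.0, height_mm=1000.0)


@dataclass(frozen=True)
class WalkerConfig:
    """Parameters of one simulated walking trial."""

    style: str = "comfortable"
    stature_mm: float = 1700.0
    thigh_fraction: float = 0.245
    shank_fraction: float = 0.246
    trunk_fraction: float = 0.30
    stride_length_mm: float = 1400.0
    stride_time_s: float = 1.047
    hip_flex_peak_deg: float = 30.3
    hip_ext_peak_deg: float = -18.8
    knee_flex_peak_deg: float = 65.7
    knee_ext_peak_deg: float = 2.5
    n_strides: int = 10
    fps: float = 60.0
    noise_px: float = 0.0
    seed: int = 0
    lateral_offset_mm: float = 0.0
    hip_width_mm: float = 200.0
    ankle_height_mm: float = 80.0
    foot_length_mm: float = 250.0
    subject_id: str = "S0"

    @classmethod
    def for_style(cls, style: str, **overrides) -> "WalkerConfig":
        """Config with published per-style defaults, then overrides."""
        try:
            base = STYLE_DEFAULTS[style]
        except KeyError:
            raise ConfigError(f"unknown gait style {style!r}") from None
        kw = dict(base)
        kw.update(overrides)
        return cls(style=style, **kw)

    def __post_init__(self) -> None:
        for name in ("stature_mm", "stride_length_mm", "stride_time_s",
                     "fps", "thigh_fraction", "shank_fraction",
                     "trunk_fraction"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be positive")
        if self.n_strides < 2:
            raise ConfigError("n_strides must be >= 2")
        for name in ("hip_flex_peak_deg", "hip_ext_peak_deg",
                     "knee_flex_peak_deg", "knee_ext_peak_deg"):
            if abs(getattr(self, name)) >= 180.0:
                raise ConfigError(f"{name} implies |angle| >= 180 deg")


# ---------------------------------------------------------------------------
# angle templates
# ---------------------------------------------------------------------------

def _hip_template(phi: np.ndarray, cfg: WalkerConfig) -> np.ndarray:
    """Hip angle over phase: cosine peaking at phase 0 (stance onset)."""
    m = 0.5 * (cfg.hip_flex_peak_deg + cfg.hip_ext_peak_deg)
    a = 0.5 * (cfg.hip_flex_peak_deg - cfg.hip_ext_peak_deg)
    return m + a * np.cos(2.0 * np.pi * phi)


def _knee_template(phi: np.ndarray, cfg: WalkerConfig) -> np.ndarray:
    """Knee angle: extension-peak plateau in stance, raised-sine swing bump."""
    phi = np.asarray(phi)
    k = np.full(phi.shape, float(cfg.knee_ext_peak_deg))
    swing = phi >= 0.5
    s = (phi[swing] - 0.5) / 0.5
    amp = cfg.knee_flex_peak_deg - cfg.knee_ext_peak_deg
    k[swing] = cfg.knee_ext_peak_deg + amp * np.sin(np.pi * s) ** 2
    return k


def _stance_rel(phi, cfg, thigh, shank):
    """Forward offset ankle-minus-hip for a stance leg at phase ``phi``."""
    h = np.radians(_hip_template(np.asarray(phi, dtype=float), cfg))
    ke = np.radians(cfg.knee_ext_peak_deg)
    return thigh * np.sin(h) + shank * np.sin(h - ke)


# ---------------------------------------------------------------------------
# walk generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedWalk:
    """A generated trial: world sequences, 3D points and exact truth."""

    cfg: WalkerConfig
    t: np.ndarray
    points3d: np.ndarray            # (F, N, 3): x forward, y up, z lateral
    side_world: PoseSequence        # (x, y)
    front_world: PoseSequence       # (z lateral, y)
    schema: NodeSchema
    truth: dict = field(default_factory=dict)

    def truth_parameters(self) -> list[GaitParameters]:
        """Exact per-cycle parameters implied by the configuration."""
        out = []
        for side in ("left", "right"):
            for _ in range(self.truth["n_cycles_per_side"]):
                out.append(GaitParameters(
                    side=side,
                    subject_id=self.cfg.subject_id,
                    step_length_mm=self.truth["step_length_mm"],
                    stride_length_mm=self.truth["stride_length_mm"],
                    stride_time_s=self.truth["stride_time_s"],
                    gait_speed_m_s=self.truth["gait_speed_m_s"],
                    hip_flex_peak_deg=self.cfg.hip_flex_peak_deg,
                    hip_ext_peak_deg=self.cfg.hip_ext_peak_deg,
                    knee_flex_peak_deg=self.cfg.knee_flex_peak_deg,
                    knee_ext_peak_deg=self.cfg.knee_ext_peak_deg,
                    hip_rom_deg=(self.cfg.hip_flex_peak_deg
                                 - self.cfg.hip_ext_peak_deg),
                    knee_rom_deg=(self.cfg.knee_flex_peak_deg
                                  - self.cfg.knee_ext_peak_deg),
                ))
        return out


def _leg_points(phi, cfg, thigh, shank, hip_xy):
    """Knee and ankle positions for a leg at phase ``phi`` (vectorized)."""
    h = np.radians(_hip_template(phi, cfg))
    k = np.radians(_knee_template(phi, cfg))
    knee = hip_xy + thigh * np.stack([np.sin(h), -np.cos(h)], axis=-1)
    sh = h - k
    ankle = knee + shank * np.stack([np.sin(sh), -np.cos(sh)], axis=-1)
    return knee, ankle


def generate_walk(cfg: WalkerConfig) -> SimulatedWalk:
    """Simulate one straight walking pass with exact ground truth."""
    T = cfg.stride_time_s
    fps = cfg.fps
    n_frames = int(np.floor(cfg.n_strides * T * fps)) + 1
    t = np.arange(n_frames) / fps

    thigh0 = cfg.thigh_fraction * cfg.stature_mm
    shank0 = cfg.shank_fraction * cfg.stature_mm
    delta0 = float(_stance_rel(0.0, cfg, thigh0, shank0)
                   - _stance_rel(0.5, cfg, thigh0, shank0))
    statue = abs(delta0) < 1e-9
    if statue:
        scale = 1.0
    else:
        scale = (cfg.stride_length_mm / 2.0) / delta0
    thigh, shank = scale * thigh0, scale * shank0
    trunk = cfg.trunk_fraction * cfg.stature_mm

    phi_r = (t / T) % 1.0
    phi_l = (phi_r + 0.5) % 1.0

    x0 = -cfg.n_strides * cfg.stride_length_mm / 2.0
    if statue:
        speed = cfg.stride_length_mm / T
        hip_x = x0 + speed * t
        hip_y = np.full_like(t, cfg.ankle_height_mm + thigh + shank)
    else:
        # hip height: the stance leg's maximal vertical extent touches the
        # ground (ankle height) at least once per stance
        grid = np.linspace(0.0, 0.5, 501)
        hg = np.radians(_hip_template(grid, cfg))
        ke = np.radians(cfg.knee_ext_peak_deg)
        extent = thigh * np.cos(hg) + shank * np.cos(hg - ke)
        H = cfg.ankle_height_mm + float(np.max(extent))
        hip_y = np.full_like(t, H)
        half_idx = np.floor(2.0 * t / T).astype(int)
        phi_sup = (2.0 * t / T) % 1.0 / 2.0
        delta = cfg.stride_length_mm / 2.0
        hip_x = (x0 + half_idx * delta
                 - _stance_rel(phi_sup, cfg, thigh, shank)
                 + _stance_rel(0.0, cfg, thigh, shank))

    hip_xy = np.stack([hip_x, hip_y], axis=-1)
    knee_r, ankle_r = _leg_points(phi_r, cfg, thigh, shank, hip_xy)
    knee_l, ankle_l = _leg_points(phi_l, cfg, thigh, shank, hip_xy)
    shoulder_xy = hip_xy + np.array([0.0, trunk])
    head_xy = hip_xy + np.array([0.0, cfg.stature_mm - thigh - shank])

    lat = cfg.lateral_offset_mm
    zr, zl = lat - cfg.hip_width_mm / 2.0, lat + cfg.hip_width_mm / 2.0
    schema = SIM_SCHEMA
    F, N = n_frames, schema.n_nodes
    pts = np.empty((F, N, 3))

    def put(label, xy, z):
        i = schema.index_of(label)
        pts[:, i, :2] = xy
        pts[:, i, 2] = z

    put("head", head_xy, lat)
    put("neck", shoulder_xy, lat)
    put("left_shoulder", shoulder_xy, zl)
    put("right_shoulder", shoulder_xy, zr)
    put("left_hip", hip_xy, zl)
    put("right_hip", hip_xy, zr)
    put("left_knee", knee_l, zl)
    put("right_knee", knee_r, zr)
    put("left_ankle", ankle_l, zl)
    put("right_ankle", ankle_r, zr)

    meta = dict(schema=schema, fps=fps, space="world_mm",
                subject_id=cfg.subject_id, stature_mm=cfg.stature_mm)
    conf = np.ones((F, N))
    missing = np.zeros((F, N), dtype=bool)
    side_world = PoseSequence(t, pts[:, :, :2].copy(), conf.copy(),
                              missing.copy(), camera_tag="side", **meta)
    front_world = PoseSequence(
        t, np.stack([pts[:, :, 2], pts[:, :, 1]], axis=-1),
        conf.copy(), missing.copy(), camera_tag="front", **meta)

    n_cycles = max(cfg.n_strides - 1, 0)
    truth = {
        "stride_length_mm": cfg.stride_length_mm,
        "step_length_mm": cfg.stride_length_mm / 2.0,
        "stride_time_s": T,
        "gait_speed_m_s": cfg.stride_length_mm / 1000.0 / T,
        "hip_flex_peak_deg": cfg.hip_flex_peak_deg,
        "hip_ext_peak_deg": cfg.hip_ext_peak_deg,
        "knee_flex_peak_deg": cfg.knee_flex_peak_deg,
        "knee_ext_peak_deg": cfg.knee_ext_peak_deg,
        "hip_rom_deg": cfg.hip_flex_peak_deg - cfg.hip_ext_peak_deg,
        "knee_rom_deg": cfg.knee_flex_peak_deg - cfg.knee_ext_peak_deg,
        "segment_scale": scale,
        "statue": statue,
        "n_cycles_per_side": n_cycles,
        "lateral_offset_mm": lat,
    }
    if not statue:
        # stance ankle x = hip_x + rel(phi) = x0 + i*delta + rel(0)
        rel0 = float(_stance_rel(0.0, cfg, thigh, shank))
        step = cfg.stride_length_mm / 2.0
        truth["placements_right_x_mm"] = [
            x0 + rel0 + i * step for i in range(0, 2 * cfg.n_strides, 2)]
        truth["placements_left_x_mm"] = [
            x0 + rel0 + i * step for i in range(1, 2 * cfg.n_strides, 2)]
    return SimulatedWalk(cfg, t, pts, side_world, front_world, schema, truth)


def generate_standing(cfg: WalkerConfig, duration_s: float = 1.0,
                      x_mm: float = 0.0) -> SimulatedWalk:
    """A standing calibration pose (straight legs) at walkway position x."""
    fps = cfg.fps
    n_frames = max(int(round(duration_s * fps)), 2)
    t = np.arange(n_frames) / fps
    thigh = cfg.thigh_fraction * cfg.stature_mm
    shank = cfg.shank_fraction * cfg.stature_mm
    trunk = cfg.trunk_fraction * cfg.stature_mm
    a0 = cfg.ankle_height_mm
    hip_y = a0 + thigh + shank
    lat = cfg.lateral_offset_mm
    zr, zl = lat - cfg.hip_width_mm / 2.0, lat + cfg.hip_width_mm / 2.0
    schema = SIM_SCHEMA
    pts = np.empty((n_frames, schema.n_nodes, 3))
    rows = {
        "head": (x_mm, a0 + cfg.stature_mm, lat),
        "neck": (x_mm, hip_y + trunk, lat),
        "left_shoulder": (x_mm, hip_y + trunk, zl),
        "right_shoulder": (x_mm, hip_y + trunk, zr),
        "left_hip": (x_mm, hip_y, zl),
        "right_hip": (x_mm, hip_y, zr),
        "left_knee": (x_mm, a0 + shank, zl),
        "right_knee": (x_mm, a0 + shank, zr),
        "left_ankle": (x_mm, a0, zl),
        "right_ankle": (x_mm, a0, zr),
    }
    for lab, (x, y, z) in rows.items():
        pts[:, schema.index_of(lab)] = (x, y, z)
    meta = dict(schema=schema, fps=fps, space="world_mm",
                subject_id=cfg.subject_id, stature_mm=cfg.stature_mm)
    conf = np.ones(pts.shape[:2])
    missing = np.zeros(pts.shape[:2], dtype=bool)
    side = PoseSequence(t, pts[:, :, :2].copy(), conf.copy(), missing.copy(),
                        camera_tag="side", **meta)
    front = PoseSequence(t, np.stack([pts[:, :, 2], pts[:, :, 1]], axis=-1),
                         conf.copy(), missing.copy(), camera_tag="front",
                         **meta)
    return SimulatedWalk(cfg, t, pts, side, front, schema,
                         truth={"standing": True})


def render_views(
    walk: SimulatedWalk,
    side_cam: CameraModel = DEFAULT_SIDE_CAMERA,
    front_cam: CameraModel = DEFAULT_FRONT_CAMERA,
    noise_px: float = 0.0,
    seed: int = 0,
    dropout: float = 0.0,
    image_size: tuple[int, int] | None = None,
) -> tuple[PoseSequence, PoseSequence]:
    """Project a simulated walk through both cameras to pixel sequences.

    The side camera looks along -z (perpendicular to the sagittal plane),
    the front camera along -x (down the walkway).  Confidences are sampled
    uniformly in [0.5, 1]; ``dropout`` is an i.i.d. per-node missing
    probability.  Nodes projected outside the image (default bounds: twice
    the principal point) are marked missing with a coverage warning.
    Deterministic under a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    pts = walk.points3d
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]

    side_pts = np.stack([x, y - side_cam.height_mm,
                         side_cam.distance_mm - z], axis=-1)
    front_pts = np.stack([z, y - front_cam.height_mm,
                          front_cam.distance_mm - x], axis=-1)

    out = []
    for cam, p, tag in ((side_cam, side_pts, "side"),
                        (front_cam, front_pts, "front")):
        px = project_to_camera(p, cam, noise_px=noise_px, rng=rng)
        missing = np.zeros(px.shape[:2], dtype=bool)
        bounds = image_size or (2.0 * cam.c[0], 2.0 * cam.c[1])
        oob = ((px[..., 0] < 0) | (px[..., 0] > bounds[0])
               | (px[..., 1] < 0) | (px[..., 1] > bounds[1]))
        if oob.any():
            warnings.warn(
                f"{tag} camera: {int(oob.sum())} keypoints out of view",
                stacklevel=2)
            missing |= oob
        if dropout > 0:
            missing |= rng.random(missing.shape) < dropout
        conf = rng.uniform(0.5, 1.0, size=missing.shape)
        pxm = px.copy()
        pxm[missing] = np.nan
        out.append(PoseSequence(
            walk.t, pxm, conf, missing, schema=walk.schema,
            fps=walk.cfg.fps, camera_tag=tag, space="pixel",
            subject_id=walk.cfg.subject_id, stature_mm=walk.cfg.stature_mm))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# paired two-system measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedSystemsConfig:
    """Paired-design generator: subject truth seen by two noisy systems."""

    n_subjects: int = 20
    true_mean: float = 700.0
    between_subject_sd: float = 10.0
    bias_additive: float = 0.0
    bias_multiplicative: float = 1.0
    error_sds: tuple[float, float] = (5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.between_subject_sd < 0 or any(s < 0 for s in self.error_sds):
            raise ConfigError("standard deviations must be non-negative")


def generate_paired(cfg: PairedSystemsConfig):
    """Sample an n x 2 paired matrix and its analytic reliability truth.

    System 1 measures the subject truth directly; system 2 adds the
    configured additive/multiplicative bias.  The returned truth dict gives
    the closed-form variance-component ICCs for the ``b = 1`` case
    (column-offset effects enter ICC(2,*) but not ICC(3,k)/alpha).
    """
    from .agreement import MeasurementMatrix  # local import, no cycle

    rng = np.random.default_rng(cfg.seed)
    tau = rng.normal(cfg.true_mean, cfg.between_subject_sd, cfg.n_subjects)
    s1 = tau + rng.normal(0.0, cfg.error_sds[0], cfg.n_subjects)
    s2 = (cfg.bias_additive + cfg.bias_multiplicative * tau
          + rng.normal(0.0, cfg.error_sds[1], cfg.n_subjects))
    m = MeasurementMatrix(np.column_stack([s1, s2]),
                          col_labels=("system1", "system2"))
    vb = cfg.between_subject_sd ** 2
    ve = 0.5 * (cfg.error_sds[0] ** 2 + cfg.error_sds[1] ** 2)
    theta2 = cfg.bias_additive ** 2 / 2.0  # column variance component, k=2
    k = 2
    truth = {
        "icc21": vb / (vb + theta2 + ve),
        "icc2k": vb / (vb + (theta2 + ve) / k),
        "icc3k": vb / (vb + ve / k),
        "alpha": vb / (vb + ve / k),
        "exact_for_b": 1.0,
    }
    return m, truth
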