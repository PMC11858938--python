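"""Keypoint data model and pose-sequence I/O.

A :class:`PoseSequence` holds per-frame 2D keypoints for one camera view,
either in image pixels (origin top-left, +u rightward, +v downward) or in
world millimetres (+x walking direction, +y up).  Missing keypoints are
carried as an explicit boolean mask; coordinates under the mask are NaN and
ignored by every downstream operation.

Two on-disk dialects are supported:

* CSV — long format, one row per (frame, node): columns ``t, node, u, v,
  conf``.  Missing keypoints have empty coordinate cells.
* JSON — per-frame node dicts keyed by schema label, plus sequence metadata.

Both round-trip losslessly through :func:`write_pose` / :func:`read_pose`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "NodeSchema",
    "PoseSequence",
    "DEFAULT_SCHEMA",
    "SIM_SCHEMA",
    "read_pose",
    "write_pose",
    "fill_gaps",
]

#: Labels every schema must provide for the pipeline to run.
REQUIRED_LABELS = (
    "head",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Confidence below this value is treated as a missing detection.
DEFAULT_CONF_FLOOR = 0.1


@dataclass(frozen=True)
class NodeSchema:
    """Ordered set of anatomical node labels.

    Parameters
    ----------
    names
        Unique node labels; must contain all of :data:`REQUIRED_LABELS`.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValidationError("node labels must be unique")
        missing = [lab for lab in REQUIRED_LABELS if lab not in names]
        if missing:
            raise ValidationError(f"schema lacks required labels: {missing}")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def index_of(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(l) for l in labels], dtype=int)


def _default_30() -> NodeSchema:
    # Pose-estimator-style layout: 25 joints + 5 facial landmarks = 30 nodes.
    facial = ("nose", "left_eye", "right_eye", "left_ear", "right_ear")
    joints = (
        "head",
        "neck",
        "left_shoulder",
        "right_shoulder",
        "left_elbow",
        "right_elbow",
        "left_wrist",
        "right_wrist",
        "left_hand",
        "right_hand",
        "chest",
        "waist",
        "left_hip",
        "right_hip",
        "left_knee",
        "right_knee",
        "left_ankle",
        "right_ankle",
        "left_heel",
        "right_heel",
        "left_toe",
        "right_toe",
        "left_thumb",
        "right_thumb",
        "pelvis",
    )
    return NodeSchema(joints + facial)


#: 30-node schema mirroring a commercial pose estimator's output layout.
DEFAULT_SCHEMA = _default_30()

#: Minimal 10-node schema used by the synthetic walker.
SIM_SCHEMA = NodeSchema(REQUIRED_LABELS)


@dataclass
class PoseSequence:
    """Timestamped per-frame keypoint arrays for one camera view.

    Attributes
    ----------
    t : (F,) float array of frame times in seconds, strictly increasing.
    xy : (F, N, 2) float array of coordinates (NaN where missing).
    conf : (F, N) float array of per-node confidences in [0, 1].
    missing : (F, N) bool mask; True entries are ignored downstream.
    filled : (F, N) bool mask of samples reconstructed by :func:`fill_gaps`.
    """

    t: np.ndarray
    xy: np.ndarray
    conf: np.ndarray
    missing: np.ndarray
    schema: NodeSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    fps: float = 30.0
    camera_tag: str = "side"
    space: str = "pixel"
    subject_id: str = "S0"
    stature_mm: float | None = None
    filled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.filled is None:
            self.filled = np.zeros_like(self.missing)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        F = len(self.t)
        N = self.schema.n_nodes
        if self.xy.shape != (F, N, 2):
            raise ValidationError(
                f"xy shape {self.xy.shape} != ({F}, {N}, 2)")
        if self.conf.shape != (F, N) or self.missing.shape != (F, N):
            raise ValidationError("conf/missing shape mismatch")
        if self.camera_tag not in ("side", "front"):
            raise ValidationError(f"bad camera_tag {self.camera_tag!r}")
        if self.space not in ("pixel", "world_mm"):
            raise ValidationError(f"bad space {self.space!r}")
        if not (self.fps > 0):
            raise ValidationError("fps must be positive")
        if F:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("frame times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fps) >= 0.5 / self.fps):
                raise ValidationError(
                    "frame spacing inconsistent with fps "
                    f"(max deviation {np.max(np.abs(dt - 1/self.fps)):.4g} s)")
        present = ~self.missing
        if not np.all(np.isfinite(self.xy[present])):
            raise ValidationError("present coordinates must be finite")
        ok = (self.conf >= 0) & (self.conf <= 1)
        if not np.all(ok | self.missing):
            raise ValidationError("confidences must lie in [0, 1]")

    # -- convenience -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.t)

    def node_xy(self, label: str) -> np.ndarray:
        """(F, 2) coordinates of one node, NaN where missing."""
        i = self.schema.index_of(label)
        out = self.xy[:, i, :].copy()
        out[self.missing[:, i]] = np.nan
        return out

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            t=self.t.copy(),
            xy=self.xy.copy(),
            conf=self.conf.copy(),
            missing=self.missing.copy(),
            filled=self.filled.copy(),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_fps(t: np.ndarray) -> float:
    if len(t) < 2:
        return 30.0
    return 1.0 / float(np.median(np.diff(t)))


def read_pose(
    path,
    schema: NodeSchema = DEFAULT_SCHEMA,
    dialect: str = "csv",
    fps: float | None = None,
    conf_floor: float = DEFAULT_CONF_FLOOR,
    **meta,
) -> PoseSequence:
    """Read a pose sequence from disk.

    ``fps=None`` infers the rate from the median frame spacing.  Rows with
    unparseable coordinates are marked missing; confidence below
    ``conf_floor`` is coerced to missing.  Unknown node labels are rejected.
    """
    if dialect == "csv":
        return _read_csv(path, schema, fps, conf_floor, meta)
    if dialect == "json":
        return _read_json(path, schema, fps, conf_floor, meta)
    raise FormatError(f"unknown dialect {dialect!r}")


def _seq_from_long(df: pd.DataFrame, schema, fps, conf_floor, meta) -> PoseSequence:
    unknown = set(df["node"]) - set(schema.names)
    if unknown:
        raise ValidationError(f"unknown node labels: {sorted(unknown)}")
    times = np.array(sorted(df["t"].unique()), dtype=float)
    if np.any(np.diff(times) <= 0):  # defensive; unique+sorted is monotone
        raise ValidationError("non-monotone timestamps")
    # detect non-monotone raw ordering: per-node t must be sorted already
    for _, g in df.groupby("node", sort=False):
        if np.any(np.diff(g["t"].to_numpy(dtype=float)) <= 0):
            raise ValidationError("non-monotone timestamps within a node track")
    F, N = len(times), schema.n_nodes
    xy = np.full((F, N, 2), np.nan)
    conf = np.zeros((F, N))
    missing = np.ones((F, N), dtype=bool)
    frame_of = {t: i for i, t in enumerate(times)}
    ni = df["node"].map({n: i for i, n in enumerate(schema.names)}).to_numpy()
    fi = df["t"].map(frame_of).to_numpy()
    u = pd.to_numeric(df["u"], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(df["v"], errors="coerce").to_numpy(dtype=float)
    c = pd.to_numeric(df["conf"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    ok = np.isfinite(u) & np.isfinite(v) & (c >= conf_floor)
    xy[fi[ok], ni[ok], 0] = u[ok]
    xy[fi[ok], ni[ok], 1] = v[ok]
    conf[fi, ni] = np.clip(c, 0.0, 1.0)
    missing[fi[ok], ni[ok]] = False
    if fps is None:
        fps = _infer_fps(times)
    return PoseSequence(times, xy, conf, missing, schema=schema, fps=fps, **meta)


def _read_csv(path, schema, fps, conf_floor, meta) -> PoseSequence:
    try:
        df = pd.read_csv(path, dtype={"node": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    required = {"t", "node", "u", "v", "conf"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"malformed header: need columns {sorted(required)}, "
            f"got {list(df.columns)}")
    if df.empty:
        return PoseSequence(
            np.empty(0), np.empty((0, schema.n_nodes, 2)),
            np.empty((0, schema.n_nodes)),
            np.empty((0, schema.n_nodes), dtype=bool),
            schema=schema, fps=fps or 30.0, **meta)
    df = df.copy()
    df["t"] = pd.to_numeric(df["t"], errors="raise")
    return _seq_from_long(df, schema, fps, conf_floor, meta)


def _read_json(path, schema, fps, conf_floor, meta) -> PoseSequence:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"cannot parse JSON {path}: {exc}") from exc
    for key in ("schema", "frames"):
        if key not in doc:
            raise FormatError(f"JSON pose file lacks key {key!r}")
    labels = list(doc["schema"])
    if labels != list(schema.names):
        unknown = set(labels) - set(schema.names)
        if unknown:
            raise ValidationError(f"unknown node labels: {sorted(unknown)}")
        raise ValidationError("JSON schema does not match requested schema")
    F, N = len(doc["frames"]), schema.n_nodes
    t = np.empty(F)
    xy = np.full((F, N, 2), np.nan)
    conf = np.zeros((F, N))
    missing = np.ones((F, N), dtype=bool)
    for i, fr in enumerate(doc["frames"]):
        t[i] = fr["t"]
        nodes = fr["nodes"]
        for j, lab in enumerate(labels):
            rec = nodes.get(lab)
            if rec is None:
                continue
            u, v, c = rec
            conf[i, j] = c
            if u is not None and v is not None and c >= conf_floor:
                xy[i, j] = (u, v)
                missing[i, j] = False
    if F and np.any(np.diff(t) <= 0):
        raise ValidationError("non-monotone timestamps")
    kw = dict(meta)
    for key in ("fps", "camera_tag", "space", "subject_id", "stature_mm"):
        if key in doc and key not in kw and doc[key] is not None:
            kw[key] = doc[key]
    if fps is not None:
        kw["fps"] = fps
    elif "fps" not in kw:
        kw["fps"] = _infer_fps(t)
    return PoseSequence(t, xy, conf, missing, schema=schema, **kw)


def write_pose(seq: PoseSequence, path, dialect: str = "csv") -> None:
    """Write a pose sequence; lossless round trip with :func:`read_pose`."""
    if dialect == "csv":
        rows = []
        for i in range(seq.n_frames):
            for j, lab in enumerate(seq.schema.names):
                if seq.missing[i, j]:
                    u = v = ""
                else:
                    u = repr(float(seq.xy[i, j, 0]))
                    v = repr(float(seq.xy[i, j, 1]))
                rows.append((repr(float(seq.t[i])), lab, u, v,
                             repr(float(seq.conf[i, j]))))
        with open(path, "w") as fh:
            fh.write("t,node,u,v,conf\n")
            for r in rows:
                fh.write(",".join(r) + "\n")
    elif dialect == "json":
        frames = []
        for i in range(seq.n_frames):
            nodes = {}
            for j, lab in enumerate(seq.schema.names):
                c = float(seq.conf[i, j])
                if seq.missing[i, j]:
                    nodes[lab] = None if c == 0.0 else [None, None, c]
                else:
                    nodes[lab] = [float(seq.xy[i, j, 0]),
                                  float(seq.xy[i, j, 1]), c]
            frames.append({"t": float(seq.t[i]), "nodes": nodes})
        doc = {
            "schema": list(seq.schema.names),
            "fps": seq.fps,
            "camera_tag": seq.camera_tag,
            "space": seq.space,
            "subject_id": seq.subject_id,
            "stature_mm": seq.stature_mm,
            "frames": frames,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def fill_gaps(seq: PoseSequence, max_gap_frames: int = 3) -> PoseSequence:
    """Linearly interpolate short missing runs, per node per axis.

    Runs of up to ``max_gap_frames`` consecutive missing frames bounded by
    present samples on both sides are filled (interpolating in time); longer
    runs and leading/trailing gaps are left missing — the operation never
    extrapolates.  Present samples are untouched, so the operation is
    idempotent.  Filled entries are flagged in ``seq.filled``.
    """
    out = seq.copy()
    F = seq.n_frames
    for j in range(seq.schema.n_nodes):
        miss = out.missing[:, j]
        if not miss.any() or miss.all():
            continue
        present_idx = np.flatnonzero(~miss)
        i = 0
        while i < F:
            if not miss[i]:
                i += 1
                continue
            start = i
            while i < F and miss[i]:
                i += 1
            end = i  # run is [start, end)
            if start == 0 or end == F:
                continue  # no extrapolation
            if end - start > max_gap_frames:
                continue
            t0, t1 = out.t[start - 1], out.t[end]
            p0, p1 = out.xy[start - 1, j], out.xy[end, j]
            w = (out.t[start:end] - t0) / (t1 - t0)
            out.xy[start:end, j] = p0 + w[:, None] * (p1 - p0)
            out.missing[start:end, j] = False
            out.filled[start:end, j] = True
        del present_idx
    return out
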