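"""Per-cycle spatiotemporal parameters, peak angles and ROM, and
table-style aggregation.

Stride time comes from the event times; stride length from the forward
distance between the successive ipsilateral foot placements surrounding the
cycle's stance; step length from the contralateral placement inside the
cycle against the preceding ipsilateral one; gait speed is
stride/stride-time, so the identity ``speed = stride_mm / 1000 /
stride_time`` holds exactly per cycle.

Aggregation follows the report layout of validation tables: each subject is
first reduced to its per-parameter mean, then the group mean and sample SD
(ddof=1) are taken across subjects.  Per-cycle pooling is available via
``by="cycle"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .events import FootPlacement, GaitCycle
from .kinematics import JointAngleSeries

__all__ = [
    "GaitParameters",
    "spatiotemporal",
    "peaks_and_rom",
    "aggregate",
    "PARAMETER_FIELDS",
]

PARAMETER_FIELDS = (
    "step_length_mm",
    "stride_length_mm",
    "stride_time_s",
    "gait_speed_m_s",
    "hip_flex_peak_deg",
    "hip_ext_peak_deg",
    "knee_flex_peak_deg",
    "knee_ext_peak_deg",
    "hip_rom_deg",
    "knee_rom_deg",
)


@dataclass
class GaitParameters:
    """Parameters of one gait cycle; NaN marks a non-computable field."""

    side: str = ""
    subject_id: str = "S0"
    step_length_mm: float = np.nan
    stride_length_mm: float = np.nan
    stride_time_s: float = np.nan
    gait_speed_m_s: float = np.nan
    hip_flex_peak_deg: float = np.nan
    hip_ext_peak_deg: float = np.nan
    knee_flex_peak_deg: float = np.nan
    knee_ext_peak_deg: float = np.nan
    hip_rom_deg: float = np.nan
    knee_rom_deg: float = np.nan
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"side": self.side, "subject_id": self.subject_id}
        d.update({f: getattr(self, f) for f in PARAMETER_FIELDS})
        return d


def spatiotemporal(
    cycles: list[GaitCycle],
    placements_by_side: dict[str, list[FootPlacement]],
    subject_id: str = "S0",
) -> list[GaitParameters]:
    """Spatiotemporal fields for each valid cycle.

    Cycles without bracketing placements get NaN spatial fields (the stride
    time is always available from the event times).
    """
    out = []
    other = {"left": "right", "right": "left"}
    for cyc in cycles:
        if not cyc.valid:
            continue
        p = GaitParameters(side=cyc.side, subject_id=subject_id)
        p.stride_time_s = cyc.duration
        ipsi = sorted(placements_by_side.get(cyc.side, []), key=lambda q: q.t)
        contra = sorted(placements_by_side.get(other[cyc.side], []),
                        key=lambda q: q.t)
        inside = [q for q in ipsi if cyc.t_start <= q.t <= cyc.t_end]
        if inside:
            p0 = inside[0]
            later = [q for q in ipsi if q.t > p0.t]
            if later:
                p.stride_length_mm = abs(later[0].x_mm - p0.x_mm)
                p.gait_speed_m_s = p.stride_length_mm / 1000.0 / p.stride_time_s
            contra_inside = [q for q in contra
                             if cyc.t_start <= q.t <= cyc.t_end and q.t > p0.t]
            if contra_inside:
                p.step_length_mm = abs(contra_inside[0].x_mm - p0.x_mm)
        out.append(p)
    return out


def peaks_and_rom(
    angles: JointAngleSeries,
    cycle: GaitCycle,
    params: GaitParameters | None = None,
) -> GaitParameters:
    """Peak flexion/extension and ROM of hip and knee within one cycle.

    Flexion peak = max of the signed in-cycle series, extension peak = min,
    ROM = max - min.  Extension magnitudes (reporting convention for hip
    extension) are stored in ``extras``.
    """
    p = params or GaitParameters(side=cycle.side)
    in_cycle = (angles.t >= cycle.t_start) & (angles.t <= cycle.t_end)
    for joint, series in (("hip", angles.hip_deg), ("knee", angles.knee_deg)):
        y = series[in_cycle]
        y = y[np.isfinite(y)]
        if y.size == 0:
            continue
        flex, ext = float(np.max(y)), float(np.min(y))
        setattr(p, f"{joint}_flex_peak_deg", flex)
        setattr(p, f"{joint}_ext_peak_deg", ext)
        setattr(p, f"{joint}_rom_deg", flex - ext)
        p.extras[f"{joint}_ext_peak_abs_deg"] = abs(ext)
    return p


def aggregate(
    per_cycle: list[GaitParameters],
    by: str = "subject",
) -> pd.DataFrame:
    """Mean/SD summary table across cycles or subjects.

    ``by="subject"`` reduces each subject to its per-parameter mean first,
    then reports the across-subject mean and sample SD; ``by="cycle"``
    pools all cycles.  With a single record per group, SD is reported as 0
    and flagged through ``n``.
    """
    if not per_cycle:
        raise ValidationError("aggregate needs at least one record")
    if by not in ("subject", "cycle"):
        raise ValidationError(f"unknown aggregation level {by!r}")
    df = pd.DataFrame([p.as_dict() for p in per_cycle])
    n_cycles = len(df)
    if by == "subject":
        df = df.groupby("subject_id", as_index=False)[list(PARAMETER_FIELDS)].mean()
    rows = []
    for f in PARAMETER_FIELDS:
        vals = df[f].dropna().to_numpy()
        if vals.size == 0:
            rows.append({"parameter": f, "mean": np.nan, "sd": np.nan,
                         "n": 0, "n_cycles": n_cycles})
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append({"parameter": f, "mean": float(np.mean(vals)), "sd": sd,
                     "n": int(vals.size), "n_cycles": n_cycles})
    return pd.DataFrame(rows)
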