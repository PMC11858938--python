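"""End-to-end convenience: world-space sequence -> per-cycle parameters.

Chains angle computation, cycle detection, foot-placement detection,
spatiotemporal parameters and peak/ROM extraction for one or both limbs.
The CLI's ``analyze`` command and the validation harness both run through
this function, so the single code path is what gets validated.
"""

from __future__ import annotations

import numpy as np

from .errors import EventDetectionError
from .events import (GaitCycle, detect_cycles, detect_foot_placements,
                     ensemble_stats, normalize_cycle)
from .kinematics import angle_series
from .params import GaitParameters, peaks_and_rom, spatiotemporal

__all__ = ["analyze_world_sequence"]


def analyze_world_sequence(
    world_seq,
    sides: tuple[str, ...] = ("left", "right"),
    v_stance: float = 100.0,
    hip_reference: str = "trunk",
    n_curve_points: int = 101,
):
    """Run events -> parameters -> normalized curves on a world sequence.

    Returns ``(per_cycle, curves)`` where ``per_cycle`` is a list of
    :class:`GaitParameters` and ``curves`` maps ``(side, joint)`` to the
    ensemble ``(phase, mean, sd, n_curves)``.  Raises
    :class:`EventDetectionError` if no limb yields two crossings.
    """
    placements = {}
    for side in sides:
        try:
            placements[side] = detect_foot_placements(
                world_seq, side, v_stance=v_stance)
        except EventDetectionError:
            placements[side] = []

    per_cycle: list[GaitParameters] = []
    curves = {}
    any_cycles = False
    for side in sides:
        try:
            cycles = detect_cycles(world_seq, side)
        except EventDetectionError:
            continue
        any_cycles = True
        angles = angle_series(world_seq, side, reference=hip_reference)
        records = spatiotemporal(cycles, placements,
                                 subject_id=world_seq.subject_id)
        valid_cycles = [c for c in cycles if c.valid]
        for cyc, rec in zip(valid_cycles, records):
            peaks_and_rom(angles, cyc, params=rec)
        per_cycle.extend(records)
        for joint in ("hip", "knee"):
            ncurves = [normalize_cycle(angles, c, joint=joint,
                                       n_points=n_curve_points)
                       for c in valid_cycles]
            ncurves = [c for c in ncurves if c.valid]
            if ncurves:
                mean, sd = ensemble_stats(ncurves)
                curves[(side, joint)] = (
                    np.linspace(0.0, 100.0, n_curve_points), mean, sd,
                    len(ncurves))
    if not any_cycles:
        raise EventDetectionError("no gait cycles detected on any limb")
    return per_cycle, curves
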