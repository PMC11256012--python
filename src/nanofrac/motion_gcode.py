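"""Timed motion plans for dip collection, and their G-code rendering.

The collector captures nano-flow effluent by holding the column outlet
~1 mm below the surface of buffer preloaded in the destination well.
A plan is a flat list of :class:`MotionCommand`; every well-to-well
transition is the fixed sequence raise-to-safe-Z -> XY transit ->
descend-to-collection-depth, and collection windows are device-timed
dwells.  The emitted dialect is a minimal Marlin-style subset
(G21/G90/G28/G1/G4/M400) as spoken by consumer 3D-printer firmware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .plate_schedule import CollectionSchedule, PlateSpec, WellAddress, well_to_xyz

__all__ = [
    "MotionParams",
    "MotionCommand",
    "PlanningError",
    "plan_motion",
    "emit_gcode",
    "plan_duration",
    "check_plan_safety",
]


class PlanningError(ValueError):
    """A schedule cannot be realized under the given motion parameters."""


@dataclass(frozen=True)
class MotionParams:
    """Kinematic settings of the collector head.

    ``dip_depth_mm`` is how far the outlet sits below the liquid surface
    while collecting (~1 mm into ~50 uL of preloaded buffer).  The slow
    ``dip_feed_mm_min`` engages ``approach_clearance_mm`` above the
    surface; all other motion runs at ``travel_feed_mm_min``.  Every
    well change must complete within ``transition_budget_s`` so the
    outlet spends at least ``interval - budget`` of each fraction window
    at collection depth.
    """

    travel_feed_mm_min: float = 3000.0
    dip_feed_mm_min: float = 300.0
    dip_depth_mm: float = 1.0
    approach_clearance_mm: float = 2.0
    transition_budget_s: float = 5.0

    def __post_init__(self) -> None:
        if self.travel_feed_mm_min <= 0 or self.dip_feed_mm_min <= 0:
            raise ValueError("feed rates must be positive")
        if self.dip_depth_mm <= 0:
            raise ValueError("dip_depth_mm must be positive")
        if self.approach_clearance_mm < 0:
            raise ValueError("approach_clearance_mm must be >= 0")
        if self.transition_budget_s <= 0:
            raise ValueError("transition_budget_s must be positive")


@dataclass(frozen=True)
class MotionCommand:
    """One timed device instruction.

    ``kind`` is one of home/move/dwell/sync.  Moves carry only the axes
    they change (``x``/``y``/``z`` may be None) plus a feed; dwells carry
    a duration.  ``planned_time_s`` is the nominal time offset from plan
    start at which the command begins.  ``fraction``/``well`` annotate
    collection dwells for run logging.
    """

    kind: str
    x: float | None = None
    y: float | None = None
    z: float | None = None
    feed_mm_min: float | None = None
    duration_s: float | None = None
    planned_time_s: float = 0.0
    fraction: int | None = None
    well: WellAddress | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("home", "move", "dwell", "sync"):
            raise ValueError(f"unknown command kind {self.kind!r}")
        if self.kind == "move" and self.feed_mm_min is None:
            raise ValueError("move requires a feed rate")
        if self.kind == "dwell" and (self.duration_s is None or self.duration_s < 0):
            raise ValueError("dwell requires a nonnegative duration")


def _move_time_s(dx: float, dy: float, dz: float, feed_mm_min: float) -> float:
    return math.sqrt(dx * dx + dy * dy + dz * dz) / (feed_mm_min / 60.0)


def _collection_z(plate: PlateSpec, motion: MotionParams) -> float:
    z = plate.liquid_surface_z_mm - motion.dip_depth_mm
    # The outlet must stay inside the liquid column; the preload implies a
    # finite depth we cannot model, but it must at least clear Z = 0.
    if z < 0:
        raise PlanningError("dip depth puts collection Z below the machine bed")
    return z


def _descend_commands(plate: PlateSpec, motion: MotionParams) -> list[MotionCommand]:
    """Safe-Z -> collection-depth descent at one well (fast, then slow)."""
    slow_from = plate.liquid_surface_z_mm + motion.approach_clearance_mm
    collect_z = _collection_z(plate, motion)
    cmds = []
    if slow_from < plate.safe_travel_z_mm:
        cmds.append(
            MotionCommand("move", z=slow_from, feed_mm_min=motion.travel_feed_mm_min)
        )
    cmds.append(MotionCommand("move", z=collect_z, feed_mm_min=motion.dip_feed_mm_min))
    return cmds


def _transition_commands(
    from_xy: tuple[float, float],
    to_xy: tuple[float, float],
    plate: PlateSpec,
    motion: MotionParams,
) -> tuple[list[MotionCommand], float]:
    """Raise -> XY transit -> descend between two wells; returns (cmds, time)."""
    cmds = [
        MotionCommand(
            "move", z=plate.safe_travel_z_mm, feed_mm_min=motion.travel_feed_mm_min
        ),
        MotionCommand(
            "move",
            x=to_xy[0],
            y=to_xy[1],
            feed_mm_min=motion.travel_feed_mm_min,
        ),
    ]
    cmds.extend(_descend_commands(plate, motion))
    collect_z = _collection_z(plate, motion)
    slow_from = min(
        plate.liquid_surface_z_mm + motion.approach_clearance_mm,
        plate.safe_travel_z_mm,
    )
    t = (
        _move_time_s(0, 0, plate.safe_travel_z_mm - collect_z, motion.travel_feed_mm_min)
        + _move_time_s(
            to_xy[0] - from_xy[0], to_xy[1] - from_xy[1], 0, motion.travel_feed_mm_min
        )
        + _move_time_s(0, 0, plate.safe_travel_z_mm - slow_from, motion.travel_feed_mm_min)
        + _move_time_s(0, 0, slow_from - collect_z, motion.dip_feed_mm_min)
    )
    return cmds, t


def plan_motion(
    schedule: CollectionSchedule,
    plate: PlateSpec | None = None,
    motion: MotionParams | None = None,
) -> list[MotionCommand]:
    """Turn a collection schedule into an ordered motion plan.

    The plan homes, approaches the first well, then for each event dwells
    at collection depth; the dwell of every event except the last is
    shortened by the exact transit time of the following raise/XY/descend
    group, so event boundaries land on schedule.  The plan ends raised at
    safe Z.  Raises :class:`PlanningError` if any transition cannot fit
    ``transition_budget_s``.
    """
    if not schedule.events:
        raise PlanningError("schedule has no events")
    plate = plate or schedule.plate
    motion = motion or MotionParams()
    if motion.transition_budget_s >= schedule.params.interval_s:
        raise PlanningError("transition_budget_s must be smaller than the interval")

    xy = {
        ev.index: well_to_xyz(ev.well, plate)[:2] for ev in schedule.events
    }
    plan: list[MotionCommand] = []
    t = 0.0

    def push(cmd: MotionCommand) -> None:
        plan.append(replace(cmd, planned_time_s=t))

    first = schedule.events[0]
    push(MotionCommand("home"))
    push(
        MotionCommand(
            "move", z=plate.safe_travel_z_mm, feed_mm_min=motion.travel_feed_mm_min
        )
    )
    push(
        MotionCommand(
            "move",
            x=xy[first.index][0],
            y=xy[first.index][1],
            feed_mm_min=motion.travel_feed_mm_min,
        )
    )
    for cmd in _descend_commands(plate, motion):
        push(cmd)
    if schedule.params.start_offset_s > 0:
        push(MotionCommand("dwell", duration_s=schedule.params.start_offset_s))
        t += schedule.params.start_offset_s

    interval = schedule.params.interval_s
    for ev, nxt in zip(schedule.events, schedule.events[1:] + (None,)):
        if nxt is None or nxt.well == ev.well:
            transit_cmds: list[MotionCommand] = []
            transit_t = 0.0
        else:
            transit_cmds, transit_t = _transition_commands(
                xy[ev.index], xy[nxt.index], plate, motion
            )
            if transit_t > motion.transition_budget_s:
                raise PlanningError(
                    f"transition after fraction {ev.index} ({ev.well}->{nxt.well}) "
                    f"takes {transit_t:.2f} s, over the {motion.transition_budget_s} s budget"
                )
        push(
            MotionCommand(
                "dwell",
                duration_s=interval - transit_t,
                fraction=ev.index,
                well=ev.well,
            )
        )
        t += interval - transit_t
        for cmd in transit_cmds:
            push(cmd)
        t += transit_t
    push(
        MotionCommand(
            "move", z=plate.safe_travel_z_mm, feed_mm_min=motion.travel_feed_mm_min
        )
    )
    return plan


# --- G-code emission ---------------------------------------------------------

_DIALECTS = ("marlin",)


def emit_gcode(plan: Sequence[MotionCommand], dialect: str = "marlin") -> list[str]:
    """Render a plan as G-code lines (deterministic text).

    Preamble sets mm units and absolute mode; every motion command is
    followed by an M400 completion sync so host-side timing is honored.
    Coordinates print with 3 decimals, feeds as integer mm/min, dwells as
    millisecond pauses.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unsupported G-code dialect {dialect!r}")
    lines = ["G21", "G90"]
    for cmd in plan:
        lines.extend(command_gcode(cmd))
    lines.append("M400")
    return lines


def command_gcode(cmd: MotionCommand) -> list[str]:
    """G-code lines for a single command (moves carry their M400 sync)."""
    if cmd.kind == "home":
        return ["G28", "M400"]
    if cmd.kind == "move":
        parts = ["G1"]
        for axis, value in (("X", cmd.x), ("Y", cmd.y), ("Z", cmd.z)):
            if value is not None:
                parts.append(f"{axis}{value:.3f}")
        parts.append(f"F{round(cmd.feed_mm_min)}")
        return [" ".join(parts), "M400"]
    if cmd.kind == "dwell":
        return [f"G4 P{round(cmd.duration_s * 1000)}"]
    return ["M400"]  # sync


def plan_duration(plan: Sequence[MotionCommand]) -> float:
    """Total nominal execution time of a plan in seconds.

    Moves contribute distance/feed (zero acceleration model, matching the
    virtual printer); dwells contribute their duration; homing is nominal
    zero.  Axes a move does not mention keep their previous value.
    """
    x = y = z = 0.0
    total = 0.0
    for cmd in plan:
        if cmd.kind == "home":
            x = y = z = 0.0
        elif cmd.kind == "move":
            nx = cmd.x if cmd.x is not None else x
            ny = cmd.y if cmd.y is not None else y
            nz = cmd.z if cmd.z is not None else z
            total += _move_time_s(nx - x, ny - y, nz - z, cmd.feed_mm_min)
            x, y, z = nx, ny, nz
        elif cmd.kind == "dwell":
            total += cmd.duration_s
    return total


def check_plan_safety(plan: Sequence[MotionCommand], plate: PlateSpec) -> None:
    """Assert that no command changes X or Y while Z is below safe-travel.

    Walks the plan tracking commanded pose; raises :class:`PlanningError`
    on the first violating command.  Homing is exempt (firmware homes one
    axis at a time against its endstop).
    """
    z = plate.safe_travel_z_mm
    x = y = None
    for i, cmd in enumerate(plan):
        if cmd.kind == "home":
            x = y = 0.0
            z = 0.0
        elif cmd.kind == "move":
            moves_xy = (cmd.x is not None and cmd.x != x) or (
                cmd.y is not None and cmd.y != y
            )
            target_z = cmd.z if cmd.z is not None else z
            if moves_xy and (z < plate.safe_travel_z_mm or target_z < plate.safe_travel_z_mm):
                raise PlanningError(
                    f"command {i} moves XY with Z below safe travel height"
                )
            x = cmd.x if cmd.x is not None else x
            y = cmd.y if cmd.y is not None else y
            z = target_z
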