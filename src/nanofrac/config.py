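"""Run configuration files.

A run config is a YAML document with up to three sections — ``plate``,
``schedule``, ``motion`` — whose keys are the corresponding dataclass
fields.  Units: lengths in mm, times in s, volumes in uL, flow in
nL/min.  Omitted keys (or sections) fall back to the defaults encoding
the canonical 40-fraction / 8-well run.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .motion_gcode import MotionParams
from .plate_schedule import PlateSpec, ScheduleParams, WellAddress

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    """Bundle of plate geometry, schedule, and motion parameters."""

    def __init__(
        self,
        plate: PlateSpec | None = None,
        schedule: ScheduleParams | None = None,
        motion: MotionParams | None = None,
    ) -> None:
        self.plate = plate or PlateSpec()
        self.schedule = schedule or ScheduleParams()
        self.motion = motion or MotionParams()


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load a YAML run config; missing sections use package defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of sections")
    unknown = set(doc) - {"plate", "schedule", "motion"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sched = dict(doc.get("schedule") or {})
    if "start_well" in sched and isinstance(sched["start_well"], str):
        sched["start_well"] = WellAddress.parse(sched["start_well"])
    if "custom_map" in sched and sched["custom_map"] is not None:
        sched["custom_map"] = {
            int(k): WellAddress.parse(v) if isinstance(v, str) else v
            for k, v in sched["custom_map"].items()
        }
    return RunConfig(
        plate=_build(PlateSpec, dict(doc.get("plate") or {}), "plate"),
        schedule=_build(ScheduleParams, sched, "schedule"),
        motion=_build(MotionParams, dict(doc.get("motion") or {}), "motion"),
    )
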