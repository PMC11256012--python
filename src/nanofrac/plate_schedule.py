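"""Destination-rack geometry and concatenation schedules.

High-pH reversed-phase fractionation collects the first-dimension eluate
into timed fractions and pools ("concatenates") non-adjacent fractions
into a small number of wells, so that each pooled well samples the whole
gradient.  The canonical scheme here is 40 one-minute fractions pooled
round-robin into 8 wells (an 8 x 5 scheme: fractions i, i+8, i+16, ...
share a well).  This module models the plate geometry and builds the
fraction -> well -> time mapping that the motion planner consumes.
"""

from __future__ import annotations

import csv
import math
import string
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PlateSpec",
    "WellAddress",
    "ScheduleParams",
    "CollectionEvent",
    "CollectionSchedule",
    "assign_well",
    "build_schedule",
    "well_to_xyz",
    "per_well_volume",
    "write_schedule_csv",
]

_ROW_LETTERS = string.ascii_uppercase


class ScheduleError(ValueError):
    """Invalid schedule parameters or fraction/well addressing."""


@dataclass(frozen=True)
class PlateSpec:
    """Physical layout of a destination rack in machine coordinates.

    Defaults describe a standard 96-well microplate (9 mm pitch, 0.2 mL
    wells) preloaded with 50 uL of LC buffer, mounted on the collector bed.
    Z references: the outlet travels at ``safe_travel_z_mm``, clears the
    rim at ``well_top_z_mm`` and collects ~1 mm below
    ``liquid_surface_z_mm`` (see the motion planner).
    """

    n_rows: int = 8
    n_cols: int = 12
    pitch_mm: float = 9.0
    origin_x_mm: float = 50.0
    origin_y_mm: float = 50.0
    well_top_z_mm: float = 40.0
    liquid_surface_z_mm: float = 30.0
    safe_travel_z_mm: float = 50.0
    well_volume_uL: float = 200.0
    preload_volume_uL: float = 50.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and one column")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        if not (self.safe_travel_z_mm > self.well_top_z_mm > self.liquid_surface_z_mm):
            raise ValueError(
                "Z references must satisfy safe_travel_z > well_top_z > liquid_surface_z"
            )
        if not (0 <= self.preload_volume_uL < self.well_volume_uL):
            raise ValueError("preload volume must be in [0, well_volume)")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True, order=True)
class WellAddress:
    """Microplate well address, row-major from A1.

    ``row`` is a capital letter ('A' = first row), ``col`` is 1-based.
    """

    row: str
    col: int

    def __post_init__(self) -> None:
        if len(self.row) != 1 or self.row not in _ROW_LETTERS:
            raise ValueError(f"row must be a single letter A-Z, got {self.row!r}")
        if self.col < 1:
            raise ValueError("col must be >= 1")

    @property
    def row_index(self) -> int:
        return _ROW_LETTERS.index(self.row)

    def linear_index(self, plate: PlateSpec) -> int:
        """Row-major 0-based index on ``plate`` (A1=0, A2=1, ...)."""
        self.validate(plate)
        return self.row_index * plate.n_cols + (self.col - 1)

    @classmethod
    def from_linear(cls, index: int, plate: PlateSpec) -> "WellAddress":
        if not 0 <= index < plate.n_wells:
            raise ScheduleError(
                f"linear index {index} outside plate with {plate.n_wells} wells"
            )
        row, col = divmod(index, plate.n_cols)
        return cls(_ROW_LETTERS[row], col + 1)

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        """Parse 'C4'-style labels."""
        text = text.strip().upper()
        if len(text) < 2 or text[0] not in _ROW_LETTERS or not text[1:].isdigit():
            raise ValueError(f"cannot parse well address {text!r}")
        return cls(text[0], int(text[1:]))

    def validate(self, plate: PlateSpec) -> None:
        if self.row_index >= plate.n_rows or self.col > plate.n_cols:
            raise ScheduleError(
                f"well {self} outside {plate.n_rows}x{plate.n_cols} plate"
            )

    def __str__(self) -> str:
        return f"{self.row}{self.col}"


PATTERNS = ("roundrobin", "blocked", "identity", "custom")


@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of one fractionation run.

    Defaults encode the canonical collection scheme: 40 fractions at
    1 min intervals concatenated into 8 main wells starting at A1.
    """

    n_fractions: int = 40
    n_wells: int = 8
    interval_s: float = 60.0
    start_offset_s: float = 0.0
    pattern: str = "roundrobin"
    start_well: WellAddress = field(default_factory=lambda: WellAddress("A", 1))
    custom_map: Mapping[int, WellAddress] | None = None

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if self.start_offset_s < 0:
            raise ValueError("start_offset_s must be >= 0")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.pattern == "identity" and self.n_wells != self.n_fractions:
            raise ValueError("identity pattern requires n_wells == n_fractions")
        if self.pattern != "custom" and not 1 <= self.n_wells <= self.n_fractions:
            raise ValueError("need 1 <= n_wells <= n_fractions for pooling patterns")
        if self.pattern == "custom" and self.custom_map is None:
            raise ValueError("custom pattern requires custom_map")


@dataclass(frozen=True)
class CollectionEvent:
    """One timed collection window bound to a destination well."""

    index: int  # 1-based fraction number
    well: WellAddress
    t_start_s: float
    t_end_s: float


@dataclass(frozen=True)
class CollectionSchedule:
    """Ordered, contiguous, non-overlapping collection events."""

    params: ScheduleParams
    plate: PlateSpec
    events: tuple[CollectionEvent, ...]

    @property
    def per_well_counts(self) -> dict[WellAddress, int]:
        counts: dict[WellAddress, int] = {}
        for ev in self.events:
            counts[ev.well] = counts.get(ev.well, 0) + 1
        return counts

    @property
    def span_s(self) -> float:
        """Total collection time from first event start to last event end."""
        return self.events[-1].t_end_s - self.events[0].t_start_s

    @property
    def wells_in_order(self) -> tuple[WellAddress, ...]:
        """Distinct destination wells in order of first use."""
        seen: dict[WellAddress, None] = {}
        for ev in self.events:
            seen.setdefault(ev.well, None)
        return tuple(seen)


def _well_offset(fraction_index: int, params: ScheduleParams) -> int:
    """0-based destination offset from the start well for one fraction."""
    i = fraction_index - 1
    if params.pattern == "roundrobin":
        return i % params.n_wells
    if params.pattern == "identity":
        return i
    if params.pattern == "blocked":
        # Balanced contiguous blocks: the first `r` wells take one extra
        # event so that per-well counts never differ by more than 1.
        q, r = divmod(params.n_fractions, params.n_wells)
        boundary = r * (q + 1)
        if i < boundary:
            return i // (q + 1)
        return r + (i - boundary) // q
    raise AssertionError(params.pattern)


def assign_well(
    fraction_index: int, params: ScheduleParams, plate: PlateSpec | None = None
) -> WellAddress:
    """Destination well of a 1-based fraction index under ``params``.

    Round-robin pools fractions i, i+n_wells, i+2*n_wells, ... into one
    well (the concatenation scheme); blocked pools contiguous runs;
    identity maps each fraction to its own well; custom follows an
    explicit map.  Wells advance row-major from ``params.start_well``.
    """
    if not 1 <= fraction_index <= params.n_fractions:
        raise ScheduleError(
            f"fraction index {fraction_index} outside 1..{params.n_fractions}"
        )
    plate = plate or PlateSpec()
    if params.pattern == "custom":
        assert params.custom_map is not None
        try:
            well = params.custom_map[fraction_index]
        except KeyError:
            raise ScheduleError(
                f"custom_map has no entry for fraction {fraction_index}"
            ) from None
        well.validate(plate)
        return well
    offset = _well_offset(fraction_index, params)
    base = params.start_well.linear_index(plate)
    return WellAddress.from_linear(base + offset, plate)


def build_schedule(
    params: ScheduleParams, plate: PlateSpec | None = None
) -> CollectionSchedule:
    """Build the full timed schedule for ``params`` on ``plate``.

    Event k occupies the half-open window
    ``[start_offset + (k-1)*interval, start_offset + k*interval)`` so no
    instant belongs to two fractions.
    """
    plate = plate or PlateSpec()
    if params.pattern != "custom":
        last = params.start_well.linear_index(plate) + (
            params.n_wells if params.pattern != "identity" else params.n_fractions
        )
        if last > plate.n_wells:
            raise ScheduleError(
                f"{params.n_wells} wells from {params.start_well} exceed plate capacity"
            )
    events = []
    for k in range(1, params.n_fractions + 1):
        t0 = params.start_offset_s + (k - 1) * params.interval_s
        events.append(
            CollectionEvent(
                index=k,
                well=assign_well(k, params, plate),
                t_start_s=t0,
                t_end_s=t0 + params.interval_s,
            )
        )
    return CollectionSchedule(params=params, plate=plate, events=tuple(events))


def well_to_xyz(well: WellAddress, plate: PlateSpec) -> tuple[float, float, float]:
    """Machine coordinates of a well center at the collection reference Z.

    X grows with column, Y with row, both at the plate pitch; Z is the
    liquid surface (the planner subtracts the dip depth).
    """
    well.validate(plate)
    x = plate.origin_x_mm + (well.col - 1) * plate.pitch_mm
    y = plate.origin_y_mm + well.row_index * plate.pitch_mm
    return (x, y, plate.liquid_surface_z_mm)


def per_well_volume(
    schedule: CollectionSchedule,
    flow_nL_min: float,
    include_preload: bool = False,
) -> tuple[dict[WellAddress, float], bool]:
    """Collected volume per well (uL) at a constant first-dimension flow.

    Returns ``(volumes, overflow)`` where ``overflow`` flags any well whose
    final volume (collected + preload) would exceed the nominal well
    capacity.  With ``include_preload`` the preloaded buffer volume is
    added to the reported numbers.
    """
    if flow_nL_min <= 0:
        raise ValueError("flow_nL_min must be positive")
    uL_per_event = schedule.params.interval_s / 60.0 * flow_nL_min / 1000.0
    preload = schedule.plate.preload_volume_uL
    volumes: dict[WellAddress, float] = {}
    overflow = False
    for well, count in schedule.per_well_counts.items():
        collected = count * uL_per_event
        if collected + preload > schedule.plate.well_volume_uL:
            overflow = True
        volumes[well] = collected + (preload if include_preload else 0.0)
    return volumes, overflow


def write_schedule_csv(schedule: CollectionSchedule, path) -> None:
    """Export a schedule as CSV: fraction,row,col,t_start_s,t_end_s."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fraction", "row", "col", "t_start_s", "t_end_s"])
        for ev in schedule.events:
            writer.writerow(
                [ev.index, ev.well.row, ev.well.col, f"{ev.t_start_s:g}", f"{ev.t_end_s:g}"]
            )
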