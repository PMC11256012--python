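"""Virtual printer and run orchestration.

The collector is built from a consumer 3D printer (a Creality Ender 5 S1
gantry), driven over a newline-terminated serial line protocol with one
acknowledgment token per command.  :class:`VirtualPrinter` emulates the
command subset the planner emits — homing, absolute moves with a modal
feed, millisecond dwells, completion sync — with a distance/feed time
model and hard axis limits, so the whole stack is testable without
hardware.  :class:`SerialDevice` speaks the same protocol over a real
port (requires the optional pyserial dependency).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

from .motion_gcode import MotionCommand, command_gcode
from .plate_schedule import WellAddress

__all__ = [
    "AxisLimits",
    "PrinterState",
    "VirtualPrinter",
    "SerialDevice",
    "RunLogEntry",
    "RunLog",
    "RunAborted",
    "virtual_execute",
    "run_plan",
    "raise_to_safe",
]

# Ender 5 S1 build volume (mm)
_DEFAULT_LIMITS = ((0.0, 220.0), (0.0, 220.0), (0.0, 280.0))
_DEFAULT_FEED_MM_MIN = 3000.0


@dataclass(frozen=True)
class AxisLimits:
    x: tuple[float, float] = _DEFAULT_LIMITS[0]
    y: tuple[float, float] = _DEFAULT_LIMITS[1]
    z: tuple[float, float] = _DEFAULT_LIMITS[2]

    def contains(self, x: float, y: float, z: float) -> bool:
        return (
            self.x[0] <= x <= self.x[1]
            and self.y[0] <= y <= self.y[1]
            and self.z[0] <= z <= self.z[1]
        )


@dataclass(frozen=True)
class PrinterState:
    """Pose, homing status and simulated clock of the virtual device."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    homed: bool = False
    feed_mm_min: float = _DEFAULT_FEED_MM_MIN
    clock_s: float = 0.0
    limits: AxisLimits = field(default_factory=AxisLimits)

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


_WORD_RE = re.compile(r"([A-Z])(-?\d+(?:\.\d+)?)")


def virtual_execute(line: str, state: PrinterState) -> tuple[str, PrinterState]:
    """Execute one G-code line against a printer state.

    Returns ``(response, new_state)``; the response is ``"ok"`` for
    accepted commands, ``"error: ..."`` otherwise.  Rejected commands
    leave the state unchanged.  Moves advance the clock by
    distance / feed; dwells by their duration.
    """
    text = line.split(";", 1)[0].strip().upper()
    if not text:
        return "ok", state
    words = dict(_WORD_RE.findall(text))
    code = text.split()[0]

    if code in ("G21", "G90", "M400"):
        # units/absolute mode are the only modes supported; sync is a
        # no-op because simulated moves complete instantly
        return "ok", state
    if code == "G28":
        return "ok", replace(state, x=0.0, y=0.0, z=0.0, homed=True)
    if code in ("G0", "G1"):
        if not state.homed:
            return "error: not homed", state
        feed = float(words["F"]) if "F" in words else state.feed_mm_min
        if feed <= 0:
            return "error: bad feed", state
        nx = float(words.get("X", state.x))
        ny = float(words.get("Y", state.y))
        nz = float(words.get("Z", state.z))
        if not state.limits.contains(nx, ny, nz):
            return f"error: target ({nx:g}, {ny:g}, {nz:g}) outside axis limits", state
        dist = ((nx - state.x) ** 2 + (ny - state.y) ** 2 + (nz - state.z) ** 2) ** 0.5
        dt = dist / (feed / 60.0)
        return "ok", replace(
            state, x=nx, y=ny, z=nz, feed_mm_min=feed, clock_s=state.clock_s + dt
        )
    if code == "G4":
        if "P" in words:
            dt = float(words["P"]) / 1000.0
        elif "S" in words:
            dt = float(words["S"])
        else:
            return "error: dwell without duration", state
        if dt < 0:
            return "error: negative dwell", state
        return "ok", replace(state, clock_s=state.clock_s + dt)
    return f"error: unsupported command {code}", state


class Device(Protocol):
    """Anything that accepts one command line and returns a response."""

    def send(self, line: str) -> str: ...


class VirtualPrinter:
    """Stateful wrapper around :func:`virtual_execute`."""

    def __init__(self, limits: AxisLimits | None = None) -> None:
        self.state = PrinterState(limits=limits or AxisLimits())

    def send(self, line: str) -> str:
        response, self.state = virtual_execute(line, self.state)
        return response

    @property
    def clock_s(self) -> float:
        return self.state.clock_s


class SerialDevice:
    """Real collector over a serial port (newline-terminated, one ack per line).

    Importing pyserial is deferred to construction so the rest of the
    package works without it.
    """

    def __init__(self, port: str, baud: int = 115200, timeout_s: float = 120.0) -> None:
        try:
            import serial
        except ImportError as exc:  # pragma: no cover - optional hardware path
            raise RuntimeError(
                "pyserial is required for real-device runs; install the "
                "'serial' extra"
            ) from exc
        self._conn = serial.Serial(port, baudrate=baud, timeout=timeout_s)

    def send(self, line: str) -> str:  # pragma: no cover - hardware path
        self._conn.write((line + "\n").encode())
        response = self._conn.readline().decode().strip()
        if not response:
            raise TimeoutError(f"no acknowledgment for {line!r}")
        return response

    def close(self) -> None:  # pragma: no cover - hardware path
        self._conn.close()


@dataclass(frozen=True)
class RunLogEntry:
    """One command/response exchange, time-stamped on the device clock."""

    t_s: float
    tx: str
    rx: str
    fraction: int | None = None
    well: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_s": round(self.t_s, 6),
                "tx": self.tx,
                "rx": self.rx,
                "fraction": self.fraction,
                "well": self.well,
            }
        )


@dataclass
class RunLog:
    entries: list[RunLogEntry] = field(default_factory=list)
    aborted: bool = False

    def to_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self.entries) + "\n"

    @property
    def final_clock_s(self) -> float:
        return self.entries[-1].t_s if self.entries else 0.0


class RunAborted(RuntimeError):
    """A device error or timeout ended the run early; carries the partial log."""

    def __init__(self, message: str, log: RunLog) -> None:
        super().__init__(message)
        self.log = log


def _clock_of(device: Device) -> float:
    return getattr(device, "clock_s", 0.0)


def raise_to_safe(
    device: Device, safe_z_mm: float, feed_mm_min: float = 3000.0
) -> list[tuple[str, str]]:
    """Raise the head to the safe-travel height (idempotent, error-tolerant).

    Used when aborting a run; safe to call repeatedly.  Returns the
    command/response exchanges.
    """
    exchanges = []
    for line in (f"G1 Z{safe_z_mm:.3f} F{round(feed_mm_min)}", "M400"):
        exchanges.append((line, device.send(line)))
    return exchanges


def run_plan(
    plan: Sequence[MotionCommand],
    device: Device | None = None,
    safe_z_mm: float | None = None,
    start_delay_s: float = 0.0,
) -> RunLog:
    """Stream a plan to a device one command at a time, awaiting each ack.

    Collection dwells are annotated with their fraction index and well in
    the log.  On any device error the run aborts: the head is raised to
    ``safe_z_mm`` (default: the highest Z the plan commands) and
    :class:`RunAborted` is raised carrying the partial log.
    ``start_delay_s`` inserts a dwell before the first command (manual or
    delayed trigger).
    """
    device = device or VirtualPrinter()
    if safe_z_mm is None:
        zs = [c.z for c in plan if c.kind == "move" and c.z is not None]
        safe_z_mm = max(zs) if zs else 0.0
    log = RunLog()

    def record(t: float, tx: str, rx: str, cmd: MotionCommand | None = None) -> None:
        log.entries.append(
            RunLogEntry(
                t_s=t,
                tx=tx,
                rx=rx,
                fraction=cmd.fraction if cmd else None,
                well=str(cmd.well) if cmd and cmd.well else None,
            )
        )

    def abort(reason: str) -> None:
        log.aborted = True
        for line, rx in raise_to_safe(device, safe_z_mm):
            record(_clock_of(device), line, rx)
        raise RunAborted(reason, log)

    record(_clock_of(device), "; run start", "")
    full_plan: list[MotionCommand] = []
    if start_delay_s > 0:
        full_plan.append(MotionCommand("dwell", duration_s=start_delay_s))
    full_plan.extend(plan)
    lines_per_cmd: list[tuple[MotionCommand | None, str]] = [
        (None, "G21"),
        (None, "G90"),
    ]
    for cmd in full_plan:
        lines_per_cmd.extend((cmd, line) for line in command_gcode(cmd))
    lines_per_cmd.append((None, "M400"))
    for cmd, line in lines_per_cmd:
        try:
            rx = device.send(line)
        except TimeoutError as exc:
            abort(str(exc))
        record(_clock_of(device), line, rx, cmd)
        if rx.startswith("error"):
            abort(f"device rejected {line!r}: {rx}")
    record(_clock_of(device), "; run end", "")
    return log
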