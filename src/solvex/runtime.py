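"""Execute a compiled schedule against a hardware backend.

The runner walks the schedule's actions in time order, sleeping on a
:class:`Clock` between them (a :class:`SimulatedClock` makes a 10-hour
protocol run in milliseconds while still driving a simulated backend's flow
integration), emitting progress records, and honoring pause / resume /
abort commands from a :class:`RunController`.

Pause semantics: all pumps stop and both valves close immediately; the run
timeline (including any soak in progress) freezes; on resume, interrupted
actuators are restored and every remaining action shifts by the pause
duration, so total soak time and delivered dose volumes are preserved.  On
abort or on any backend actuation fault the runner drives the safe state —
valves closed, pumps off, keeping the tissue submerged in whatever liquid is
present — and finalizes the log with status ``aborted`` or ``faulted``.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from typing import Callable, Literal

from .errors import ActuationError
from .schedule import Action, DeviceConfig, DeviceSchedule
from .virtual import COMPONENTS, HardwareBackend

Status = Literal["completed", "aborted", "faulted"]


# ---------------------------------------------------------------------------
# Clocks
# ---------------------------------------------------------------------------


class Clock:
    """Monotone clock contract: ``now()`` seconds and ``sleep(dt)``."""

    def now(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sleep(self, dt: float) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class SimulatedClock(Clock):
    """Clock that advances instantly; drives simulated time."""

    def __init__(self) -> None:
        self._t = 0.0

    def now(self) -> float:
        return self._t

    def sleep(self, dt: float) -> None:
        if dt > 0:
            self._t += dt


class RealTimeClock(Clock):
    """Wall-clock time, optionally accelerated by ``speedup``."""

    def __init__(self, speedup: float = 1.0) -> None:
        self._t0 = _time.monotonic()
        self.speedup = speedup

    def now(self) -> float:
        return (_time.monotonic() - self._t0) * self.speedup

    def sleep(self, dt: float) -> None:
        if dt > 0:
            _time.sleep(dt / self.speedup)


# ---------------------------------------------------------------------------
# Run controller (pause / resume / abort)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptedCommand:
    time: float  # clock seconds from run start at which the command fires
    command: Literal["pause", "resume", "abort"]


class RunController:
    """Command channel into a running protocol.

    Commands can be issued programmatically (``pause()`` / ``resume()`` /
    ``abort()``, e.g. from another thread watching a keypad) or pre-scripted
    at run-timeline times, which is how tests and simulations exercise them.
    """

    def __init__(self, script: list[ScriptedCommand] | None = None) -> None:
        self._script = sorted(script or [], key=lambda c: c.time)
        self._pending: list[str] = []

    def pause(self) -> None:
        self._pending.append("pause")

    def resume(self) -> None:
        self._pending.append("resume")

    def abort(self) -> None:
        self._pending.append("abort")

    def next_scripted_time(self) -> float | None:
        return self._script[0].time if self._script else None

    def pop_due(self, clock_time: float) -> list[str]:
        due = [c.command for c in self._script if c.time <= clock_time + 1e-9]
        self._script = self._script[len(due):]
        due.extend(self._pending)
        self._pending.clear()
        return due


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogRecord:
    time: float
    kind: str  # "action" | "progress" | "command" | "warning" | "fault"
    detail: dict

    def to_json(self) -> str:
        return json.dumps({"t": round(self.time, 3), "kind": self.kind, **self.detail})


@dataclass
class RunLog:
    """Append-only, timestamped record of one executed run."""

    records: list[LogRecord] = field(default_factory=list)
    status: Status = "completed"

    def append(self, time: float, kind: str, **detail) -> None:
        self.records.append(LogRecord(time, kind, detail))

    def actions(self) -> list[LogRecord]:
        return [r for r in self.records if r.kind == "action"]

    def to_jsonl(self) -> str:
        lines = [r.to_json() for r in self.records]
        lines.append(json.dumps({"final_status": self.status}))
        return "\n".join(lines) + "\n"


ProgressCallback = Callable[[dict], None]


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def _apply_action(device: HardwareBackend, kind: str, target: str) -> None:
    if kind == "pump_on":
        device.pump_on(int(target.removeprefix("pump")))
    elif kind == "pump_off":
        device.pump_off(int(target.removeprefix("pump")))
    elif kind == "top_valve_open":
        device.top_valve(True)
    elif kind == "top_valve_close":
        device.top_valve(False)
    elif kind == "drain_open":
        device.drain(True)
    elif kind == "drain_close":
        device.drain(False)
    elif kind == "soak_wait":
        pass  # timing marker; the wait itself is the gap to the next action
    else:  # pragma: no cover - schedule compiler emits only known kinds
        raise ActuationError(f"unknown action kind {kind}")


def _safe_state(device: HardwareBackend, log: RunLog, t: float) -> None:
    device.all_off()
    log.append(t, "action", action="safe_state", target="all")


def run(
    schedule: DeviceSchedule,
    device: HardwareBackend,
    clock: Clock | None = None,
    controller: RunController | None = None,
    progress: ProgressCallback | None = None,
) -> RunLog:
    """Execute ``schedule`` on ``device``; returns the :class:`RunLog`.

    ``clock`` defaults to a :class:`SimulatedClock`.  Progress records carry
    the current step, its target concentration, elapsed run time and the
    estimated time remaining — the same readout the device display shows.
    """
    clock = clock or SimulatedClock()
    controller = controller or RunController()
    log = RunLog()
    total = schedule.total_wall_time_estimate

    # actuators currently engaged, so pause can suspend and resume restore
    pumps_running: set[str] = set()
    valves_open: set[str] = set()
    offset = 0.0  # accumulated pause time: action at t executes at t + offset
    paused = False
    pause_started = 0.0
    current_step = 0

    def emit_progress(run_t: float) -> None:
        if current_step < len(schedule.per_step_summaries):
            summ = schedule.per_step_summaries[current_step]
            rec = {
                "step": current_step + 1,
                "n_steps": len(schedule.per_step_summaries),
                "target_concentration": summ.target_concentration,
                "elapsed_s": round(run_t, 1),
                "remaining_s": round(max(total + offset - run_t, 0.0), 1),
            }
            log.append(run_t, "progress", **rec)
            if progress is not None:
                progress(rec)

    def handle_commands(run_t: float) -> Literal["continue", "abort"]:
        nonlocal paused, pause_started, offset
        for cmd in controller.pop_due(run_t):
            log.append(run_t, "command", command=cmd)
            if cmd == "abort":
                _safe_state(device, log, run_t)
                log.status = "aborted"
                return "abort"
            if cmd == "pause" and not paused:
                paused = True
                pause_started = run_t
                device.all_off()
                log.append(run_t, "action", action="pause_hold", target="all")
            elif cmd == "resume" and paused:
                paused = False
                offset += clock.now() - pause_started
                for p in sorted(pumps_running):
                    device.pump_on(int(p.removeprefix("pump")))
                    log.append(clock.now(), "action", action="pump_on", target=p)
                for v in sorted(valves_open):
                    kind = "top_valve_open" if v == "top_valve" else "drain_open"
                    _apply_action(device, kind, v)
                    log.append(clock.now(), "action", action=kind, target=v)
        return "continue"

    # sentinel so the final soak is waited out before the run completes
    end_marker = Action(schedule.total_wall_time_estimate, "run_end", "controller")

    try:
        for action in [*schedule.actions, end_marker]:
            # wait until the action is due, waking for scripted commands
            while True:
                now = clock.now()
                target_t = action.start_time + offset
                nxt = controller.next_scripted_time()
                if paused:
                    wake = nxt if nxt is not None else now + 0.25
                else:
                    wake = target_t if nxt is None else min(target_t, nxt)
                if wake > now:
                    clock.sleep(wake - now)
                    if not paused:
                        device.advance(wake - now)
                if handle_commands(clock.now()) == "abort":
                    return log
                if not paused and clock.now() >= action.start_time + offset - 1e-9:
                    break

            if action.kind == "run_end":
                break
            if action.step_index is not None and action.step_index > current_step:
                current_step = action.step_index
            _apply_action(device, action.kind, action.target)
            if action.kind == "pump_on":
                pumps_running.add(action.target)
            elif action.kind == "pump_off":
                pumps_running.discard(action.target)
            elif action.kind.endswith("_open"):
                valves_open.add(action.target)
            elif action.kind.endswith("_close"):
                valves_open.discard(action.target)
            log.append(
                clock.now(),
                "action",
                action=action.kind,
                target=action.target,
                step=None if action.step_index is None else action.step_index + 1,
                scheduled_t=action.start_time,
            )
            if action.kind == "soak_wait":
                emit_progress(clock.now())
    except ActuationError as exc:
        t = clock.now()
        log.append(t, "fault", error=str(exc))
        _safe_state(device, log, t)
        log.status = "faulted"
        return log

    log.status = "completed"
    emit_progress(clock.now())
    return log


# ---------------------------------------------------------------------------
# Utilities: flush and sanity check
# ---------------------------------------------------------------------------


def flush_system(
    device: HardwareBackend,
    config: DeviceConfig = DeviceConfig(),
    duration: float = 60.0,
    clock: Clock | None = None,
) -> RunLog:
    """Open all valves and run all pumps simultaneously for ``duration`` s.

    Used to rinse tubing and containers after a protocol; on the virtual
    device everything drains to waste, leaving both containers empty.
    """
    if not duration > 0:
        raise ValueError("flush duration must be > 0")
    clock = clock or SimulatedClock()
    log = RunLog()
    t0 = clock.now()
    try:
        for s in config.stocks:
            device.pump_on(s.pump_id)
            log.append(clock.now(), "action", action="pump_on", target=f"pump{s.pump_id}")
        device.top_valve(True)
        log.append(clock.now(), "action", action="top_valve_open", target="top_valve")
        device.drain(True)
        log.append(clock.now(), "action", action="drain_open", target="drain_valve")
        clock.sleep(duration)
        device.advance(duration)
        for s in config.stocks:
            device.pump_off(s.pump_id)
            log.append(clock.now(), "action", action="pump_off", target=f"pump{s.pump_id}")
        device.top_valve(False)
        log.append(clock.now(), "action", action="top_valve_close", target="top_valve")
        device.drain(False)
        log.append(clock.now(), "action", action="drain_close", target="drain_valve")
    except ActuationError as exc:
        t = clock.now()
        log.append(t, "fault", error=str(exc))
        _safe_state(device, log, t)
        log.status = "faulted"
        return log
    log.status = "completed"
    return log


@dataclass(frozen=True)
class ComponentStatus:
    component: str
    status: str  # "OK" or a fault description

    @property
    def ok(self) -> bool:
        return self.status == "OK"


def replay_log(log: RunLog, device: HardwareBackend) -> None:
    """Re-apply a run log's actions, with their timing, to a fresh backend.

    Replaying a completed run against an identically configured simulator
    reproduces its final state, which makes logs a self-contained record of
    what the device did.
    """
    t = 0.0
    for rec in log.actions():
        if rec.time > t:
            device.advance(rec.time - t)
            t = rec.time
        action = rec.detail["action"]
        if action in ("safe_state", "pause_hold"):
            device.all_off()
        elif action != "soak_wait":
            _apply_action(device, action, rec.detail["target"])


def sanity_check(device: HardwareBackend) -> list[ComponentStatus]:
    """Self-test every component in a fixed order (pumps 1-3, top valve,
    drain valve, input device), mirroring the device's diagnostic mode that
    reports e.g. "Pump 1 OK" per component."""
    return [ComponentStatus(c, device.self_test(c)) for c in COMPONENTS]
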