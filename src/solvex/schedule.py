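"""Compile a solvent-exchange routine into a timed actuation schedule.

Each routine step expands into four phases: *dose* (pumps run sequentially,
blending the step's target concentration into the premix container),
*transfer* (top ball valve opens; gravity moves the premix into the tissue
container), *soak* (the programmed incubation), and *drain* (bottom valve
empties the tissue container to waste).  By default the premix for step k+1
is prepared during step k's soak ("prefetch"), so the tissue container is
refilled immediately after draining and the tissue is exposed to air only
for the short drain/refill transition; a strictly serial mode is available.

All action times are quantized to the controller tick (default 0.1 s); the
residual dosing-volume error introduced by quantization is recorded on each
step summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .dosing import (
    DEFAULT_CALIBRATION,
    DEFAULT_STOCKS,
    DosePlan,
    PumpCalibration,
    StockSolution,
    blend,
)
from .errors import CompileError, UnreachableConcentrationError
from .protocol import Routine, validate_routine

ACTION_KINDS = (
    "pump_on",
    "pump_off",
    "top_valve_open",
    "top_valve_close",
    "drain_open",
    "drain_close",
    "soak_wait",
)


@dataclass(frozen=True)
class DeviceConfig:
    """Static device parameters shared by the compiler and the runtime.

    ``transfer_flow_rate`` models the gravity-driven premix→tissue fill; it
    is a configuration value (the instrument does not measure it), as is
    ``drain_time``, the window the bottom valve is held open.
    """

    stocks: tuple[StockSolution, ...] = DEFAULT_STOCKS
    exchange_volume: float = 250.0  # mL delivered per step
    tissue_capacity: float = 300.0  # mL
    transfer_flow_rate: float = 10.0  # mL/s, gravity fill
    drain_time: float = 30.0  # s the drain valve stays open
    valve_actuation_latency: float = 2.0  # s
    controller_tick: float = 0.1  # s
    prefetch: bool = True  # premix step k+1 during step k's soak

    def __post_init__(self) -> None:
        if self.exchange_volume > self.tissue_capacity:
            raise CompileError(
                f"exchange_volume {self.exchange_volume} mL exceeds tissue "
                f"container capacity {self.tissue_capacity} mL"
            )
        if self.controller_tick <= 0 or self.transfer_flow_rate <= 0:
            raise CompileError("controller_tick and transfer_flow_rate must be > 0")

    @property
    def transfer_time(self) -> float:
        """Top-valve open window: fill time plus actuation latency, s."""
        return self.exchange_volume / self.transfer_flow_rate + self.valve_actuation_latency


@dataclass(frozen=True)
class Action:
    """One timed actuation command."""

    start_time: float  # s from run start
    kind: str
    target: str  # component id, e.g. "pump2", "top_valve"
    payload: float | None = None  # duration (soak_wait) or dose volume (pump_on)
    step_index: int | None = None  # 0-based routine step this belongs to


@dataclass(frozen=True)
class StepSummary:
    step_index: int
    target_concentration: float
    dose_plan: DosePlan
    soak_seconds: float
    soak_start: float
    soak_end: float
    quantization_volume_error: float  # mL lost/gained by tick rounding


@dataclass
class DeviceSchedule:
    routine_id: int
    actions: list[Action]
    per_step_summaries: list[StepSummary]
    total_soak_time: float
    total_wall_time_estimate: float
    warnings: list[str] = field(default_factory=list)

    def actions_of_kind(self, kind: str) -> list[Action]:
        return [a for a in self.actions if a.kind == kind]


def _quantize(t: float, tick: float) -> float:
    """Round to the controller tick (half-up), avoiding float drift."""
    return round(round(t / tick) * tick, 9)


def compile_routine(
    routine: Routine,
    config: DeviceConfig = DeviceConfig(),
    calibration: PumpCalibration = DEFAULT_CALIBRATION,
) -> DeviceSchedule:
    """Compile ``routine`` into a :class:`DeviceSchedule`.

    Raises :class:`CompileError` naming the offending step for empty
    routines or unreachable concentrations.
    """
    report = validate_routine(routine, config)
    if not report.ok:
        first = report.violations[0]
        raise CompileError(
            f"routine {routine.routine_id} invalid: {first.message}"
        )

    tick = config.controller_tick
    plans: list[DosePlan] = []
    for i, step in enumerate(routine.steps):
        try:
            plans.append(
                blend(
                    step.target_concentration,
                    config.exchange_volume,
                    config.stocks,
                    calibration,
                )
            )
        except UnreachableConcentrationError as exc:  # pragma: no cover - guarded above
            raise CompileError(f"step {i + 1}: {exc}") from exc

    actions: list[Action] = []
    summaries: list[StepSummary] = []
    warnings: list[str] = []

    def dose_actions(plan: DosePlan, t0: float, step_idx: int) -> tuple[float, float]:
        """Emit sequential pump on/off pairs; return (end time, vol error)."""
        t = _quantize(t0, tick)
        vol_err = 0.0
        for entry in plan.entries:
            run = _quantize(entry.pump_time, tick)
            delivered = run * calibration.flow_rate / calibration.scale_factor
            vol_err += delivered - entry.volume
            actions.append(
                Action(t, "pump_on", f"pump{entry.stock.pump_id}", entry.volume, step_idx)
            )
            t = _quantize(t + run, tick)
            actions.append(Action(t, "pump_off", f"pump{entry.stock.pump_id}", None, step_idx))
        return t, vol_err

    transfer_window = _quantize(config.transfer_time, tick)
    drain_window = _quantize(config.drain_time, tick)

    # step 0 dose happens up front; later doses either prefetch during the
    # previous soak or run serially after the previous drain.
    t = 0.0
    premix_ready = 0.0  # time the premix for the upcoming step is ready
    vol_errs = [0.0] * len(routine.steps)
    premix_ready, vol_errs[0] = dose_actions(plans[0], 0.0, 0)

    for i, step in enumerate(routine.steps):
        # transfer: open the top valve once premix is ready and (for i>0) the
        # previous drain has finished
        t_open = _quantize(max(t, premix_ready), tick)
        actions.append(Action(t_open, "top_valve_open", "top_valve", None, i))
        t_close = _quantize(t_open + transfer_window, tick)
        actions.append(Action(t_close, "top_valve_close", "top_valve", None, i))

        soak_start = t_close
        soak_s = _quantize(step.duration_s, tick)
        actions.append(Action(soak_start, "soak_wait", "controller", soak_s, i))
        soak_end = _quantize(soak_start + soak_s, tick)

        if i + 1 < len(routine.steps):
            if config.prefetch:
                premix_ready, vol_errs[i + 1] = dose_actions(plans[i + 1], soak_start, i + 1)
                if premix_ready > soak_end:
                    warnings.append(
                        f"step {i + 2}: premix dosing ({premix_ready - soak_start:.0f} s) "
                        f"outlasts step {i + 1}'s soak ({soak_s:.0f} s); refill is delayed"
                    )
            else:
                premix_ready = math.inf  # placeholder, set after drain

        if i + 1 < len(routine.steps):
            # drain to waste, then the next step's transfer refills
            actions.append(Action(soak_end, "drain_open", "drain_valve", None, i))
            drain_end = _quantize(soak_end + drain_window, tick)
            actions.append(Action(drain_end, "drain_close", "drain_valve", None, i))
            t = drain_end
        else:
            # after the final soak the tissue stays submerged for retrieval
            t = soak_end

        if i + 1 < len(routine.steps) and not config.prefetch:
            premix_ready, vol_errs[i + 1] = dose_actions(plans[i + 1], drain_end, i + 1)

        summaries.append(
            StepSummary(
                step_index=i,
                target_concentration=step.target_concentration,
                dose_plan=plans[i],
                soak_seconds=soak_s,
                soak_start=soak_start,
                soak_end=soak_end,
                quantization_volume_error=vol_errs[i],
            )
        )

    actions.sort(key=lambda a: (a.start_time, _close_before_open(a)))
    total_soak = sum(s.soak_seconds for s in summaries)
    return DeviceSchedule(
        routine_id=routine.routine_id,
        actions=actions,
        per_step_summaries=summaries,
        total_soak_time=total_soak,
        total_wall_time_estimate=t,
        warnings=warnings,
    )


def _close_before_open(a: Action) -> int:
    """At equal timestamps, closing/stopping actions execute first."""
    return 0 if a.kind in ("pump_off", "top_valve_close", "drain_close") else 1


def format_schedule(schedule: DeviceSchedule) -> str:
    """Human-readable action timeline (used by ``solvex schedule show``)."""
    lines = [
        f"routine {schedule.routine_id}: {len(schedule.per_step_summaries)} steps, "
        f"total soak {schedule.total_soak_time / 3600:.2f} h, "
        f"est. wall time {schedule.total_wall_time_estimate / 3600:.2f} h"
    ]
    for w in schedule.warnings:
        lines.append(f"  warning: {w}")
    for a in schedule.actions:
        extra = ""
        if a.kind == "pump_on" and a.payload is not None:
            extra = f"  ({a.payload:.1f} mL)"
        elif a.kind == "soak_wait" and a.payload is not None:
            extra = f"  ({a.payload / 60:.1f} min)"
        step = f"step {a.step_index + 1}" if a.step_index is not None else ""
        lines.append(f"  t={a.start_time:10.1f}s  {a.kind:<16} {a.target:<12} {step}{extra}")
    return "\n".join(lines)
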