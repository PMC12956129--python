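"""Hardware backend contract and the virtual (simulated) device.

The real instrument has three peristaltic pumps feeding a premix container,
a motorized top ball valve that gravity-transfers the premix into the tissue
container, and a servo-driven bottom drain valve emptying the tissue
container into a waste bottle.  :class:`HardwareBackend` is the contract any
driver must honor; :class:`VirtualDevice` implements it as a mass-balance
simulator with perfect instantaneous mixing, optional per-pump flow noise,
and fault injection for exercising diagnostics and safe-state handling.

Flow integration is event-driven with exact piecewise-linear flows: within
an interval where the actuator set is constant, every container volume is
linear in time, so ``advance`` subdivides only at cutoff events (a stock
bottle running dry, the premix emptying mid-transfer, a drain completing, a
container reaching capacity) and incurs no numerical ODE error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal, Protocol, runtime_checkable

import numpy as np

from .dosing import DEFAULT_CALIBRATION, DEFAULT_STOCKS, StockSolution
from .errors import ActuationError, SimulationFault

PUMP_IDS = (1, 2, 3)
COMPONENTS = ("pump1", "pump2", "pump3", "top_valve", "drain_valve", "input")

_MASS_TOL = 1e-6


@runtime_checkable
class HardwareBackend(Protocol):
    """Contract a hardware driver must honor.

    Commands are idempotent (opening an open valve is a no-op) and
    ``self_test`` has no lasting side effects.  ``advance`` exists so a
    simulated backend can integrate its internal flows as simulated time
    passes; real drivers implement it as a no-op.
    """

    def pump_on(self, pump_id: int) -> None: ...

    def pump_off(self, pump_id: int) -> None: ...

    def top_valve(self, open_: bool) -> None: ...

    def drain(self, open_: bool) -> None: ...

    def self_test(self, component: str) -> str: ...

    def advance(self, dt: float) -> None: ...

    def all_off(self) -> None: ...


@dataclass
class ContainerState:
    """Liquid held by one container, tracked as total and ethanol volume."""

    volume: float = 0.0  # mL
    ethanol: float = 0.0  # mL of ethanol within `volume`
    capacity: float = 300.0  # mL

    @property
    def concentration(self) -> float:
        """Ethanol volume fraction; 0 for an empty container."""
        return self.ethanol / self.volume if self.volume > 1e-12 else 0.0


@dataclass(frozen=True)
class Fault:
    component: str
    mode: Literal["dead", "degraded"]
    rate_multiplier: float = 1.0  # for degraded components


@dataclass
class Snapshot:
    """Immutable copy of the observable simulator state."""

    time: float
    premix_volume: float
    premix_concentration: float
    tissue_volume: float
    tissue_concentration: float
    waste_volume: float
    stock_levels: dict[str, float]
    pumps_on: tuple[int, ...]
    top_valve_open: bool
    drain_open: bool


class VirtualDevice:
    """Mass-balance simulator of the two-container processor.

    Parameters
    ----------
    stocks : sequence of StockSolution
        Stock reservoirs; ``pump_id`` maps each to its pump.
    initial_stock_volume : float
        Starting level of every stock bottle, mL.  The operator fills bottles
        to match the protocol's demand; multi-step protocols need more than
        the 1000 mL default.
    pump_rate : float
        Nominal pump flow rate, mL/s (the calibrated 1.10 by default).
    pump_rate_sd : float
        Per-dispense Gaussian SD of the realized rate (0 = ideal pump).  A
        fresh rate is drawn each time a pump switches on, mimicking
        dispense-to-dispense variability.
    transfer_flow_rate, drain_flow_rate : float
        Gravity premix→tissue and tissue→waste flow rates, mL/s.
    drain_residual_fraction : float
        Fraction of the tissue volume left behind by a drain (0 = complete
        drain); exists for sensitivity tests.
    """

    def __init__(
        self,
        stocks: tuple[StockSolution, ...] = DEFAULT_STOCKS,
        *,
        initial_stock_volume: float = 1000.0,
        premix_capacity: float = 400.0,
        tissue_capacity: float = 300.0,
        pump_rate: float = DEFAULT_CALIBRATION.flow_rate,
        pump_rate_sd: float = 0.0,
        transfer_flow_rate: float = 10.0,
        drain_flow_rate: float = 25.0,
        drain_residual_fraction: float = 0.0,
        stock_warning_level: float = 100.0,
        seed: int | None = None,
    ) -> None:
        self.stocks = tuple(sorted(stocks, key=lambda s: s.concentration))
        self.stock_levels: dict[int, float] = {
            s.pump_id: float(initial_stock_volume) for s in self.stocks
        }
        self._stock_by_pump = {s.pump_id: s for s in self.stocks}
        self.premix = ContainerState(capacity=premix_capacity)
        self.tissue = ContainerState(capacity=tissue_capacity)
        self.waste_volume = 0.0
        self.waste_ethanol = 0.0
        self.pump_rate = pump_rate
        self.pump_rate_sd = pump_rate_sd
        self.transfer_flow_rate = transfer_flow_rate
        self.drain_flow_rate = drain_flow_rate
        self.drain_residual_fraction = drain_residual_fraction
        self.stock_warning_level = stock_warning_level
        self.rng = np.random.default_rng(seed)
        self.time = 0.0
        self.pumps_on: dict[int, float] = {}  # pump_id -> realized rate
        self.top_valve_open = False
        self.drain_open = False
        self._drain_floor = 0.0
        self.fault_set: dict[str, Fault] = {}
        self.warnings: list[str] = []
        self._initial_total = sum(self.stock_levels.values())
        self._initial_ethanol = sum(
            self.stock_levels[s.pump_id] * s.concentration for s in self.stocks
        )

    # -- backend commands ---------------------------------------------------

    def _check_alive(self, component: str) -> float:
        f = self.fault_set.get(component)
        if f is None:
            return 1.0
        if f.mode == "dead":
            raise ActuationError(f"{component} is dead")
        return f.rate_multiplier

    def pump_on(self, pump_id: int) -> None:
        if pump_id not in self._stock_by_pump:
            raise ActuationError(f"unknown pump {pump_id}")
        if pump_id in self.pumps_on:  # idempotent
            return
        mult = self._check_alive(f"pump{pump_id}")
        rate = self.pump_rate * mult
        if self.pump_rate_sd > 0:
            rate = max(float(self.rng.normal(rate, self.pump_rate_sd * mult)), 0.0)
        self.pumps_on[pump_id] = rate

    def pump_off(self, pump_id: int) -> None:
        if pump_id not in self._stock_by_pump:
            raise ActuationError(f"unknown pump {pump_id}")
        self.pumps_on.pop(pump_id, None)

    def top_valve(self, open_: bool) -> None:
        if open_ != self.top_valve_open:
            self._check_alive("top_valve")
            self.top_valve_open = open_

    def drain(self, open_: bool) -> None:
        if open_ != self.drain_open:
            self._check_alive("drain_valve")
            self.drain_open = open_
            if open_:
                self._drain_floor = self.drain_residual_fraction * self.tissue.volume

    def all_off(self) -> None:
        """Safe state: pumps off, both valves closed.  Never raises."""
        self.pumps_on.clear()
        self.top_valve_open = False
        self.drain_open = False

    def self_test(self, component: str) -> str:
        if component not in COMPONENTS:
            raise ActuationError(f"unknown component {component!r}")
        f = self.fault_set.get(component)
        if f is None:
            return "OK"
        if f.mode == "dead":
            return "FAULT: no response"
        return f"FAULT: degraded (x{f.rate_multiplier:g})"

    # -- fault injection ----------------------------------------------------

    def inject_fault(
        self,
        component: str,
        mode: Literal["dead", "degraded"],
        rate_multiplier: float = 1.0,
    ) -> None:
        if component not in COMPONENTS:
            raise ActuationError(f"unknown component {component!r}")
        self.fault_set[component] = Fault(component, mode, rate_multiplier)
        if mode == "dead" and component.startswith("pump"):
            self.pumps_on.pop(int(component[4:]), None)

    def clear_faults(self) -> None:
        self.fault_set.clear()

    # -- flow integration ---------------------------------------------------

    def _flows(self) -> tuple[dict[int, float], float, float]:
        """Current (pump inflows, transfer rate, drain rate), all mL/s."""
        pump_flows = {
            pid: rate
            for pid, rate in self.pumps_on.items()
            if self.stock_levels[pid] > 1e-12
        }
        inflow = sum(pump_flows.values())
        transfer_cap = (
            self.transfer_flow_rate * self._check_mult("top_valve")
            if self.top_valve_open
            else 0.0
        )
        # an empty premix with the valve open passes pump inflow straight through
        transfer = (
            transfer_cap if self.premix.volume > 1e-12 else min(transfer_cap, inflow)
        )
        drain_cap = (
            self.drain_flow_rate * self._check_mult("drain_valve")
            if self.drain_open
            else 0.0
        )
        drain = (
            drain_cap
            if self.tissue.volume > self._drain_floor + 1e-12
            else min(drain_cap, transfer)
        )
        return pump_flows, transfer, drain

    def _check_mult(self, component: str) -> float:
        f = self.fault_set.get(component)
        return f.rate_multiplier if f is not None and f.mode == "degraded" else 1.0

    def advance(self, dt: float) -> None:
        """Integrate flows over ``dt`` seconds (exact, event-subdivided)."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        remaining = dt
        for _ in range(10_000):  # hard stop against pathological loops
            if remaining <= 1e-12:
                break
            pump_flows, transfer, drain = self._flows()
            step = remaining
            # time until a stock runs dry
            for pid, q in pump_flows.items():
                step = min(step, self.stock_levels[pid] / q)
            # premix: net rate and time to empty / overfill
            premix_net = sum(pump_flows.values()) - transfer
            if premix_net < -1e-12:
                step = min(step, self.premix.volume / -premix_net)
            elif premix_net > 1e-12:
                step = min(step, (self.premix.capacity - self.premix.volume) / premix_net)
            # tissue: net rate and time to hit drain floor / overfill
            tissue_net = transfer - drain
            if tissue_net < -1e-12:
                step = min(
                    step, (self.tissue.volume - self._drain_floor) / -tissue_net
                )
            elif tissue_net > 1e-12:
                step = min(step, (self.tissue.capacity - self.tissue.volume) / tissue_net)
            step = max(step, 0.0)
            self._integrate_constant(step, pump_flows, transfer, drain)
            remaining -= step
            if step == 0.0 and self._overflow_imminent(pump_flows, transfer, drain):
                raise SimulationFault(
                    f"container overflow at t={self.time:.1f}s "
                    f"(premix {self.premix.volume:.1f}/{self.premix.capacity:.0f} mL, "
                    f"tissue {self.tissue.volume:.1f}/{self.tissue.capacity:.0f} mL)"
                )
            if step == 0.0:
                # all flows are cut off; nothing changes for the rest of dt
                self.time += remaining
                remaining = 0.0
        self._assert_mass_balance()

    def _overflow_imminent(self, pump_flows, transfer, drain) -> bool:
        premix_net = sum(pump_flows.values()) - transfer
        tissue_net = transfer - drain
        return (
            premix_net > 1e-12
            and self.premix.capacity - self.premix.volume <= 1e-9
        ) or (
            tissue_net > 1e-12
            and self.tissue.capacity - self.tissue.volume <= 1e-9
        )

    def _integrate_constant(self, dt: float, pump_flows, transfer, drain) -> None:
        if dt <= 0:
            return
        # stock -> premix, perfect mixing
        for pid, q in pump_flows.items():
            vol = q * dt
            conc = self._stock_by_pump[pid].concentration
            self.stock_levels[pid] -= vol
            self.premix.volume += vol
            self.premix.ethanol += vol * conc
            if (
                self.stock_levels[pid] < self.stock_warning_level
                and f"stock pump{pid} low" not in self.warnings
            ):
                self.warnings.append(f"stock pump{pid} low")
        # premix -> tissue (carries premix concentration)
        if transfer > 0:
            vol = transfer * dt
            frac = self.premix.concentration
            self.premix.volume -= vol
            self.premix.ethanol -= vol * frac
            self.tissue.volume += vol
            self.tissue.ethanol += vol * frac
        # tissue -> waste
        if drain > 0:
            vol = drain * dt
            frac = self.tissue.concentration
            self.tissue.volume -= vol
            self.tissue.ethanol -= vol * frac
            self.waste_volume += vol
            self.waste_ethanol += vol * frac
        # clamp tiny negative residues from float arithmetic
        for c in (self.premix, self.tissue):
            if -1e-9 < c.volume < 0:
                c.volume = 0.0
            if -1e-9 < c.ethanol < 0:
                c.ethanol = 0.0
        for pid in list(self.stock_levels):
            if -1e-9 < self.stock_levels[pid] < 0:
                self.stock_levels[pid] = 0.0
        self.time += dt

    def _assert_mass_balance(self) -> None:
        total = (
            sum(self.stock_levels.values())
            + self.premix.volume
            + self.tissue.volume
            + self.waste_volume
        )
        if abs(total - self._initial_total) > _MASS_TOL:
            raise SimulationFault(
                f"volume balance violated: {total:.9f} != {self._initial_total:.9f}"
            )
        ethanol = (
            sum(
                self.stock_levels[s.pump_id] * s.concentration for s in self.stocks
            )
            + self.premix.ethanol
            + self.tissue.ethanol
            + self.waste_ethanol
        )
        if abs(ethanol - self._initial_ethanol) > _MASS_TOL:
            raise SimulationFault(
                f"ethanol balance violated: {ethanol:.9f} != {self._initial_ethanol:.9f}"
            )

    # -- observation --------------------------------------------------------

    def snapshot(self) -> Snapshot:
        return Snapshot(
            time=self.time,
            premix_volume=self.premix.volume,
            premix_concentration=self.premix.concentration,
            tissue_volume=self.tissue.volume,
            tissue_concentration=self.tissue.concentration,
            waste_volume=self.waste_volume,
            stock_levels={
                self._stock_by_pump[pid].name or str(pid): lvl
                for pid, lvl in self.stock_levels.items()
            },
            pumps_on=tuple(sorted(self.pumps_on)),
            top_valve_open=self.top_valve_open,
            drain_open=self.drain_open,
        )

    def copy(self) -> "VirtualDevice":
        return copy.deepcopy(self)
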