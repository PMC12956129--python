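"""Pump dosing calibration and stock-solution blending.

The processor delivers solvent volumes open-loop: a peristaltic pump is run
for ``volume / flow_rate`` seconds, with the flow rate estimated once from
timed dispense measurements (run the pump for a fixed interval, measure the
dispensed volume in a graduated cylinder).  Each exchange step's target
ethanol concentration is realized by blending two stock solutions in the
premix container; with the default stocks (water, 70% and 100% ethanol) the
two *adjacent* stocks bracketing the target are used, which minimizes
consumption of absolute ethanol.

Mixing is treated as volume-additive: the small excess-volume contraction of
ethanol/water mixtures is ignored, since the graded-series concentrations
are nominal labels and the device has no densitometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, UnreachableConcentrationError

_EXACT_TOL = 1e-9


@dataclass(frozen=True)
class DispenseMeasurement:
    """One calibration point: pump run time (s) and dispensed volume (mL)."""

    run_time: float
    dispensed_volume: float

    def __post_init__(self) -> None:
        if not self.run_time > 0:
            raise CalibrationError(f"run_time must be > 0, got {self.run_time}")
        if self.dispensed_volume < 0:
            raise CalibrationError("dispensed_volume must be >= 0")

    @property
    def rate(self) -> float:
        """Per-measurement flow rate, mL/s."""
        return self.dispensed_volume / self.run_time


@dataclass(frozen=True)
class PumpCalibration:
    """Calibrated volumetric flow rate of one (or all) peristaltic pumps.

    Attributes
    ----------
    flow_rate : float
        Mean of per-measurement volume/time ratios, mL/s.
    flow_rate_sd : float
        Sample SD of those per-measurement rates (0 when n = 1), mL/s.
    n_measurements : int
    scale_factor : float
        Dimensionless multiplier on delivered volume, adjustable from the
        device's Calibrate menu (e.g. for a different pump model); default 1.
    """

    flow_rate: float
    flow_rate_sd: float = 0.0
    n_measurements: int = 0
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise CalibrationError(f"flow_rate must be > 0, got {self.flow_rate}")
        if self.flow_rate_sd < 0 or not self.scale_factor > 0:
            raise CalibrationError("flow_rate_sd must be >= 0 and scale_factor > 0")


#: The calibration the device ships with: 1.10 +/- 0.02 mL/s from 24 timed
#: dispenses (8 intervals x 3 replicates).
DEFAULT_CALIBRATION = PumpCalibration(flow_rate=1.10, flow_rate_sd=0.02, n_measurements=24)


@dataclass(frozen=True, order=True)
class StockSolution:
    """A stock reservoir connected to one pump."""

    concentration: float  # ethanol volume fraction in [0, 1]
    name: str = ""
    pump_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.concentration <= 1.0:
            raise CalibrationError(
                f"stock concentration must be in [0, 1], got {self.concentration}"
            )


#: Typical stock set: distilled water, 70% ethanol, absolute ethanol.
DEFAULT_STOCKS = (
    StockSolution(0.0, "Water", 1),
    StockSolution(0.70, "EtOH70", 2),
    StockSolution(1.0, "EtOH100", 3),
)


@dataclass(frozen=True)
class DoseEntry:
    stock: StockSolution
    volume: float  # mL
    pump_time: float  # s


@dataclass(frozen=True)
class DosePlan:
    """Per-stock volumes (and pump run times) realizing one step's target."""

    entries: tuple[DoseEntry, ...]
    total_volume: float
    achieved_concentration: float

    def volume_of(self, stock_name: str) -> float:
        return sum(e.volume for e in self.entries if e.stock.name == stock_name)


def estimate_flow_rate(
    measurements: Sequence[DispenseMeasurement],
) -> PumpCalibration:
    """Estimate the pump flow rate as the mean of volume/time ratios.

    This is exactly the device's calibration computation: each measurement
    contributes one rate ``dispensed_volume / run_time``; the calibration is
    their mean and sample SD.  ``scale_factor`` is left at 1.
    """
    if not measurements:
        raise CalibrationError("at least one dispense measurement is required")
    rates = np.array([m.rate for m in measurements], dtype=float)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return PumpCalibration(
        flow_rate=float(np.mean(rates)),
        flow_rate_sd=sd,
        n_measurements=int(rates.size),
    )


def estimate_flow_rate_regression(
    measurements: Sequence[DispenseMeasurement],
) -> PumpCalibration:
    """Alternative estimator: least-squares slope of volume vs time through
    the origin.  Provided for comparison; :func:`estimate_flow_rate` is the
    device's default."""
    if not measurements:
        raise CalibrationError("at least one dispense measurement is required")
    t = np.array([m.run_time for m in measurements], dtype=float)
    v = np.array([m.dispensed_volume for m in measurements], dtype=float)
    slope = float(t @ v / (t @ t))
    if not slope > 0:
        raise CalibrationError("non-positive fitted flow rate")
    resid_rates = v / t
    sd = float(np.std(resid_rates, ddof=1)) if t.size > 1 else 0.0
    return PumpCalibration(flow_rate=slope, flow_rate_sd=sd, n_measurements=int(t.size))


def pump_time_for_volume(volume: float, calibration: PumpCalibration) -> float:
    """Pump run time (s) delivering ``volume`` mL; unrounded.

    ``t = volume * scale_factor / flow_rate``.  Quantization to the
    controller tick happens at schedule compilation, not here.
    """
    if volume < 0:
        raise CalibrationError(f"volume must be >= 0, got {volume}")
    return volume * calibration.scale_factor / calibration.flow_rate


def read_dispense_csv(source: str | io.TextIOBase) -> list[DispenseMeasurement]:
    """Read calibration measurements from CSV with header ``run_time_s,volume_ml``."""
    df = pd.read_csv(source)
    missing = {"run_time_s", "volume_ml"} - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        DispenseMeasurement(run_time=float(r.run_time_s), dispensed_volume=float(r.volume_ml))
        for r in df.itertuples()
    ]


def generate_dispense_measurements(
    true_rate: float = 1.10,
    rate_sd: float = 0.02,
    run_times: Sequence[float] = (10, 20, 30, 40, 50, 60, 70, 80),
    replicates: int = 3,
    seed: int | None = None,
) -> list[DispenseMeasurement]:
    """Simulate a calibration session.

    For each run time and replicate, the realized per-dispense rate is drawn
    from a Gaussian ``N(true_rate, rate_sd)`` and the dispensed volume is
    ``rate * run_time`` — the noise model matching the device's observed
    dispense-to-dispense variability (SD 0.02 mL/s around 1.10 mL/s).
    Defaults reproduce the 8-interval x 3-replicate (n = 24) session used to
    calibrate the instrument.
    """
    rng = np.random.default_rng(seed)
    out: list[DispenseMeasurement] = []
    for t in run_times:
        rates = rng.normal(true_rate, rate_sd, size=replicates)
        out.extend(
            DispenseMeasurement(run_time=float(t), dispensed_volume=float(max(r, 0.0) * t))
            for r in rates
        )
    return out


# ---------------------------------------------------------------------------
# Stock blending
# ---------------------------------------------------------------------------

BlendStrategy = Callable[[float, Sequence[StockSolution]], tuple[StockSolution, StockSolution]]


def adjacent_bracketing(
    target: float, stocks: Sequence[StockSolution]
) -> tuple[StockSolution, StockSolution]:
    """Pick the two adjacent stocks whose concentrations bracket the target.

    With stocks {0, 70, 100}% this blends water + 70% for targets below 70%
    and 70% + 100% above, minimizing absolute-ethanol use.  ``stocks`` must
    be sorted ascending by concentration.
    """
    for lo, hi in zip(stocks, stocks[1:]):
        if lo.concentration - _EXACT_TOL <= target <= hi.concentration + _EXACT_TOL:
            return lo, hi
    raise UnreachableConcentrationError(
        f"target {target:.3f} outside stock range "
        f"[{stocks[0].concentration:.2f}, {stocks[-1].concentration:.2f}]"
    )


def blend(
    target_concentration: float,
    total_volume: float,
    stocks: Sequence[StockSolution] = DEFAULT_STOCKS,
    calibration: PumpCalibration = DEFAULT_CALIBRATION,
    strategy: BlendStrategy = adjacent_bracketing,
) -> DosePlan:
    """Solve the two-stock dilution problem for one exchange step.

    If the target matches a stock concentration (within 1e-9) the plan draws
    only from that stock; otherwise the two bracketing stocks are mixed with

        v_hi = V * (c_t - c_lo) / (c_hi - c_lo),   v_lo = V - v_hi

    so that the volume-weighted concentration equals the target exactly.
    """
    if not stocks:
        raise CalibrationError("no stock solutions configured")
    stocks = sorted(stocks, key=lambda s: s.concentration)
    concs = [s.concentration for s in stocks]
    if len(set(np.round(concs, 9))) != len(concs):
        raise CalibrationError("stock concentrations must be pairwise distinct")
    if not total_volume > 0:
        raise CalibrationError(f"total_volume must be > 0, got {total_volume}")
    lo_c, hi_c = concs[0], concs[-1]
    if not (lo_c - _EXACT_TOL <= target_concentration <= hi_c + _EXACT_TOL):
        raise UnreachableConcentrationError(
            f"target {target_concentration:.3f} outside stock range [{lo_c:.2f}, {hi_c:.2f}]"
        )

    for s in stocks:  # exact single-stock match
        if abs(s.concentration - target_concentration) <= _EXACT_TOL:
            entries = (
                DoseEntry(s, total_volume, pump_time_for_volume(total_volume, calibration)),
            )
            return DosePlan(entries, total_volume, s.concentration)

    lo, hi = strategy(target_concentration, stocks)
    v_hi = total_volume * (target_concentration - lo.concentration) / (
        hi.concentration - lo.concentration
    )
    v_lo = total_volume - v_hi
    entries = tuple(
        DoseEntry(s, v, pump_time_for_volume(v, calibration))
        for s, v in ((lo, v_lo), (hi, v_hi))
        if v > _EXACT_TOL
    )
    achieved = sum(e.stock.concentration * e.volume for e in entries) / total_volume
    return DosePlan(entries, total_volume, achieved)
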