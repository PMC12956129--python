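"""Device configuration files (YAML or JSON).

Example::

    exchange_volume: 250
    transfer_flow_rate: 10
    drain_time: 30
    valve_actuation_latency: 2
    controller_tick: 0.1
    prefetch: true
    stocks:
      - {name: Water,   concentration_pct: 0,   pump_id: 1}
      - {name: EtOH70,  concentration_pct: 70,  pump_id: 2}
      - {name: EtOH100, concentration_pct: 100, pump_id: 3}
"""

from __future__ import annotations

import dataclasses
import json

import yaml

from .dosing import PumpCalibration, StockSolution
from .errors import ProtocolError
from .schedule import DeviceConfig

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(DeviceConfig)} - {"stocks"}


def load_device_config(path: str) -> DeviceConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ProtocolError(f"config file {path!r} must hold a mapping")
    kwargs = {k: raw[k] for k in _CONFIG_FIELDS if k in raw}
    if "stocks" in raw:
        kwargs["stocks"] = tuple(
            sorted(
                (
                    StockSolution(
                        concentration=float(s["concentration_pct"]) / 100.0,
                        name=str(s.get("name", "")),
                        pump_id=int(s.get("pump_id", i + 1)),
                    )
                    for i, s in enumerate(raw["stocks"])
                ),
                key=lambda s: s.concentration,
            )
        )
    return DeviceConfig(**kwargs)


def save_calibration(calibration: PumpCalibration, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(calibration), fh, indent=2)
        fh.write("\n")


def load_calibration(path: str) -> PumpCalibration:
    with open(path, encoding="utf-8") as fh:
        return PumpCalibration(**json.load(fh))
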