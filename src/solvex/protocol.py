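"""Solvent-exchange routines and their on-disk JSON store.

The device keeps all protocols in a single JSON document (on the real
instrument it lives on an SD card, editable either through the keypad menu or
on a PC).  A *routine* is an ordered list of steps, each a target ethanol
concentration to soak the tissue in and a soak duration.  This module defines
those domain types, the (de)serialization to the store format, validation
against a device configuration, and the two built-in propidium-iodide (PI)
staining routines used throughout the test suite as fixtures.

Store schema (format_version 1)::

    {"format_version": 1,
     "routines": [{"id": 1, "name": "...",
                   "steps": [{"concentration_pct": 50, "duration_min": 30},
                             ...]}]}

Concentrations are stored as percent (matching the device display) and
exposed as volume fractions in [0, 1] in code.  Unknown keys are ignored on
read and never emitted on write.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ProtocolError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .schedule import DeviceConfig

FORMAT_VERSION = 1


class Step(BaseModel):
    """One solvent-exchange step: soak at ``target_concentration`` for ``duration``.

    Parameters
    ----------
    target_concentration : float
        Ethanol volume fraction in [0, 1] of the solution the tissue soaks in.
    duration : float
        Soak time in minutes, strictly positive and finite.
    """

    model_config = ConfigDict(frozen=True)

    target_concentration: float = Field(ge=0.0, le=1.0)
    duration: float = Field(gt=0.0)

    @field_validator("duration", "target_concentration")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("must be finite")
        return v

    @property
    def duration_s(self) -> float:
        """Soak duration in seconds."""
        return self.duration * 60.0


class Routine(BaseModel):
    """A named, ordered sequence of solvent-exchange steps.

    ``routine_id`` is the positive integer the operator selects on the device
    ("Routine ID"); it must be unique within a :class:`ProtocolStore`.
    """

    model_config = ConfigDict(frozen=True)

    routine_id: int = Field(gt=0)
    name: str = ""
    steps: tuple[Step, ...] = ()

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[Step]:  # type: ignore[override]
        return iter(self.steps)

    @property
    def total_soak_min(self) -> float:
        return sum(s.duration for s in self.steps)


@dataclass
class ProtocolStore:
    """In-memory image of the device's JSON routine store."""

    routines: dict[int, Routine] = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    def add(self, routine: Routine) -> None:
        if routine.routine_id in self.routines:
            raise ProtocolError(f"duplicate routine id {routine.routine_id}")
        self.routines[routine.routine_id] = routine

    def __len__(self) -> int:
        return len(self.routines)

    def __getitem__(self, routine_id: int) -> Routine:
        try:
            return self.routines[routine_id]
        except KeyError:
            raise ProtocolError(f"no routine with id {routine_id}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProtocolStore):
            return NotImplemented
        return (
            self.format_version == other.format_version
            and self.routines == other.routines
        )


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``step_index`` is None for routine-level issues."""

    code: str
    message: str
    step_index: int | None = None


@dataclass(frozen=True)
class ValidationReport:
    routine_id: int
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_routine(routine: Routine, config: "DeviceConfig") -> ValidationReport:
    """Check a routine against the achievable stock-concentration range.

    Never raises on a parseable routine: all findings are report entries.
    Flags empty routines, non-positive durations (defensively: the pydantic
    model already rejects them at parse time) and step concentrations outside
    ``[min stock, max stock]``.
    """
    violations: list[Violation] = []
    if not routine.steps:
        violations.append(Violation("empty-routine", "routine has no steps"))
    concs = [s.concentration for s in config.stocks]
    lo, hi = (min(concs), max(concs)) if concs else (math.nan, math.nan)
    for i, step in enumerate(routine.steps):
        if not concs or not (lo - 1e-9 <= step.target_concentration <= hi + 1e-9):
            violations.append(
                Violation(
                    "unreachable-concentration",
                    f"step {i + 1}: target {step.target_concentration:.2f} outside "
                    f"stock range [{lo:.2f}, {hi:.2f}]",
                    step_index=i,
                )
            )
        if step.duration <= 0:
            violations.append(
                Violation(
                    "non-positive duration",
                    f"step {i + 1}: duration {step.duration} min is not positive",
                    step_index=i,
                )
            )
    return ValidationReport(routine.routine_id, tuple(violations))


# ---------------------------------------------------------------------------
# JSON store (de)serialization
# ---------------------------------------------------------------------------


def read_protocol_store(document: str) -> ProtocolStore:
    """Parse a JSON protocol-store document.

    Raises :class:`ProtocolError` naming the byte offset for malformed JSON,
    or the offending routine/step for schema violations.  Unknown keys are
    ignored.
    """
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ProtocolError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(raw, dict) or not isinstance(raw.get("routines"), list):
        raise ProtocolError("document must be an object with a 'routines' list")
    store = ProtocolStore(format_version=int(raw.get("format_version", FORMAT_VERSION)))
    for r in raw["routines"]:
        rid = r.get("id") if isinstance(r, dict) else None
        try:
            steps = tuple(
                Step(
                    target_concentration=float(s["concentration_pct"]) / 100.0,
                    duration=float(s["duration_min"]),
                )
                for s in r["steps"]
            )
            routine = Routine(routine_id=int(r["id"]), name=str(r.get("name", "")), steps=steps)
        except (KeyError, TypeError, ValueError) as exc:
            raise ProtocolError(f"invalid routine {rid!r}: {exc}") from exc
        store.add(routine)
    return store


def write_protocol_store(store: ProtocolStore) -> str:
    """Serialize a store to its canonical JSON text.

    Output is deterministic (fixed key order, routines sorted by id, 2-space
    indent) so files diff cleanly; :func:`read_protocol_store` inverts it.
    Concentrations are written as percent, trimmed to integers when exact.
    """

    def _pct(fraction: float) -> float | int:
        pct = fraction * 100.0
        rounded = round(pct)
        return rounded if abs(pct - rounded) < 1e-9 else pct

    def _num(x: float) -> float | int:
        return int(x) if float(x).is_integer() else x

    doc = {
        "format_version": store.format_version,
        "routines": [
            {
                "id": r.routine_id,
                "name": r.name,
                "steps": [
                    {
                        "concentration_pct": _pct(s.target_concentration),
                        "duration_min": _num(s.duration),
                    }
                    for s in r.steps
                ],
            }
            for r in sorted(store.routines.values(), key=lambda r: r.routine_id)
        ],
    }
    return json.dumps(doc, indent=2) + "\n"


def load_protocol_store(path: str) -> ProtocolStore:
    with open(path, encoding="utf-8") as fh:
        return read_protocol_store(fh.read())


def save_protocol_store(store: ProtocolStore, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_protocol_store(store))


# ---------------------------------------------------------------------------
# Built-in PI staining routines
# ---------------------------------------------------------------------------

#: Dehydration/rehydration graded ethanol series (percent), 30 min each:
#: up 50→100%, twice at absolute ethanol, back down to two DI-water washes.
DEHYDRATION_REHYDRATION_PCT = (50, 70, 85, 95, 100, 100, 95, 85, 70, 50, 30, 15, 0, 0)

#: Post-stain re-dehydration series (percent), 30 min each: two DI-water
#: washes then up the graded series, ending with two absolute-ethanol steps.
POST_STAIN_PCT = (0, 0, 15, 30, 50, 70, 85, 95, 100, 100)


def builtin_pi_routines() -> ProtocolStore:
    """The two PI-staining routines shipped with the device.

    Routine 1 ("PI dehydration/rehydration"): 14 steps; routine 2 ("PI
    post-stain"): 10 steps; every step soaks 30 minutes.  Together they
    cover the >20 sequential solvent exchanges of the full PI workflow.
    """
    store = ProtocolStore()
    for rid, name, series in (
        (1, "PI dehydration/rehydration", DEHYDRATION_REHYDRATION_PCT),
        (2, "PI post-stain", POST_STAIN_PCT),
    ):
        store.add(
            Routine(
                routine_id=rid,
                name=name,
                steps=tuple(
                    Step(target_concentration=p / 100.0, duration=30.0) for p in series
                ),
            )
        )
    return store
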