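"""Exception hierarchy for the solvent-exchange controller."""


class SolvexError(Exception):
    """Base class for all package errors."""


class ProtocolError(SolvexError):
    """Malformed or schema-violating protocol store document."""


class UnreachableConcentrationError(SolvexError):
    """Target ethanol fraction lies outside the configured stock range."""


class CalibrationError(SolvexError):
    """Invalid or insufficient pump calibration data."""


class CompileError(SolvexError):
    """A routine cannot be compiled into a device schedule."""


class ActuationError(SolvexError):
    """A hardware backend command failed (dead component, overflow...)."""


class SimulationFault(ActuationError):
    """A fault raised by the virtual device during flow integration."""


class ProfileError(SolvexError):
    """An intensity profile is unusable (e.g. all-zero background)."""
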