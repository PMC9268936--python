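"""Exception hierarchy for wristbia."""


class WristbiaError(Exception):
    """Base class for all package errors."""


class FrequencyRangeError(WristbiaError, ValueError):
    """A dielectric table was queried outside its tabulated grid."""


class ConfigurationError(WristbiaError, ValueError):
    """Inconsistent or incomplete model / run configuration."""


class NonPhysicalSampleError(WristbiaError, ValueError):
    """An impedance sample violates passivity (Re(Z) <= 0)."""


class GridMismatchError(WristbiaError, ValueError):
    """Two sweeps do not share a frequency grid."""


class EstimationError(WristbiaError, ValueError):
    """Diameter estimation failed (e.g. negative cross-sectional area)."""


class ProtocolError(WristbiaError, ValueError):
    """A pump protocol is missing sweeps or is otherwise malformed."""


class SolverError(WristbiaError, RuntimeError):
    """The field solver failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
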