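"""Exception hierarchy for the measurement pipeline.

Each stage raises a subclass of :class:`NeodrsError` so the orchestrator can
attach the stage name and a remedy hint without string-matching messages.
"""


class NeodrsError(Exception):
    """Base class for all package errors."""


class GridError(NeodrsError):
    """Wavelength axis is non-monotonic, empty, or outside the working band."""


class SpectrumParseError(NeodrsError):
    """A spectrum file could not be parsed; message carries the line number."""


class InsufficientOverlapError(NeodrsError):
    """Spectra share less than the minimum wavelength overlap for alignment."""


class SignalError(NeodrsError):
    """Non-positive dark-corrected signal: acquisition fault (saturation,
    lamp off, probe lift-off)."""


class CoverageError(NeodrsError):
    """Requested wavelength lies outside the spectrum's grid."""


class GateRejectionError(NeodrsError):
    """Strict-mode rejection: absorbance at the gate wavelength is outside
    the configured window; re-acquire with corrected probe geometry."""


class FitFailureError(NeodrsError):
    """Optimizer did not converge; ``best`` carries the last iterate."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class DegenerateDataError(NeodrsError):
    """Input has no usable variation (constant column, zero-area component)."""


class CalibrationError(NeodrsError):
    """Calibration file missing, malformed, or family/analyte mismatch."""


class ValidationError(NeodrsError):
    """Precondition on an operation's input was violated."""
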