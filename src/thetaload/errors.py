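"""Exception hierarchy.

Every error raised by the library derives from :class:`ThetaLoadError` so callers
(and the CLI) can distinguish library failures from programming errors.
"""


class ThetaLoadError(Exception):
    """Base class for all thetaload errors."""


class FormatError(ThetaLoadError):
    """A file could not be parsed as the expected format (EDF/BDF/CSV)."""


class ValidationError(ThetaLoadError):
    """Input data violates a structural invariant (overlapping intervals, ...)."""


class ConfigurationError(ThetaLoadError):
    """A detector parameter is outside its admissible range."""


class TooShortError(ThetaLoadError):
    """The recording is too short for the requested filter or window."""


class CalibrationError(ThetaLoadError):
    """No complete averaging window fits inside the calibration span."""


class InsufficientDataError(ThetaLoadError):
    """Fewer metric values than the averaging window requires."""


class PipelineError(ThetaLoadError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
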