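"""Exception hierarchy shared across the package."""


class RivalcallError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(RivalcallError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(RivalcallError, ValueError):
    """An input file or record failed validation; message lists offenders."""


class DegenerateSignalError(RivalcallError, ValueError):
    """A waveform is silent, too short, or otherwise yields no features."""


class CalibrationRequiredError(RivalcallError, ValueError):
    """An absolute-level quantity was requested without a calibration."""


class InfeasibleTargetError(RivalcallError, ValueError):
    """A stimulus-modification target cannot be realised (e.g. overlapping pulses)."""


class DegeneratePredictorError(RivalcallError, ValueError):
    """A regression predictor is constant or has too few points."""
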