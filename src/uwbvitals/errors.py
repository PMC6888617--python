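"""Exception hierarchy for the uwbvitals pipeline."""


class UWBVitalsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(UWBVitalsError, ValueError):
    """Input data violates a precondition (non-finite, non-positive, wrong shape...)."""


class InvalidConfigError(UWBVitalsError, ValueError):
    """A configuration value is out of its valid range."""


class NoTargetError(UWBVitalsError):
    """No target can be located (all-zero energy profile, zero target energy)."""


class OutOfRangeError(UWBVitalsError, IndexError):
    """A range-bin index falls outside the calibrated detection range."""


class CalibrationError(UWBVitalsError):
    """The human energy standard cannot be built from the supplied recordings."""


class ModeSelectionError(UWBVitalsError):
    """No decomposed mode falls inside a required physiological frequency band."""

    def __init__(self, band: str, message: str | None = None):
        self.band = band
        super().__init__(message or f"no mode with center frequency in the {band} band")


class UndefinedFrequencyError(UWBVitalsError):
    """A spectral quantity (center frequency, peak rate) is undefined for this input."""


class UndefinedRatioError(UWBVitalsError):
    """An energy ratio is undefined because the denominator signal has zero energy."""


class FormatError(UWBVitalsError):
    """A radar-cube file or its metadata sidecar is malformed."""


class PipelineError(UWBVitalsError):
    """A pipeline stage failed; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
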