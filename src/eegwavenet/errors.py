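"""Exception types raised across the package."""


class EEGError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EEGError):
    """A file could not be read as the expected format."""


class InvalidRecordingError(EEGError):
    """A recording violates a structural invariant (e.g. zero channels)."""


class ParameterError(EEGError, ValueError):
    """A parameter is out of its valid range (e.g. filter cutoff >= Nyquist)."""


class MontageError(EEGError):
    """A bipolar montage cannot be derived; carries the missing electrodes."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "missing electrodes for montage derivation: " + ", ".join(self.missing)
        )


class TooShortError(EEGError):
    """A recording is shorter than the requested segment length."""

    def __init__(self, duration_s: float, required_s: float):
        self.duration_s = float(duration_s)
        self.required_s = float(required_s)
        super().__init__(
            f"recording is {duration_s:.3f} s long; {required_s:.3f} s required"
        )


class StratificationError(EEGError):
    """A stratified split or balanced sampler needs both classes present."""


class UndefinedMetricError(EEGError):
    """A confusion-matrix metric has a zero denominator."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' is undefined: zero denominator")


class EmptyDatasetError(EEGError):
    """An operation received zero recordings or zero segments."""
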