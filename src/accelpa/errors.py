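"""Exception hierarchy for the accelpa pipeline.

All package-specific failures derive from :class:`AccelpaError` so callers
(notably the CLI) can distinguish user/data errors from genuine bugs.
"""


class AccelpaError(Exception):
    """Base class for all accelpa errors."""


class SignalFormatError(AccelpaError):
    """A signal file does not conform to the expected CSV dialect."""


class SignalTimingError(AccelpaError):
    """Sample timestamps are not uniformly spaced at the declared rate."""


class SignalParseError(AccelpaError):
    """A data row contains a non-numeric or otherwise unparseable value."""


class UnsupportedRateError(AccelpaError):
    """A resampling operation received a sampling rate it cannot handle."""


class AnnotationError(AccelpaError):
    """Invalid direct-observation annotation (e.g. overlapping events)."""


class DegenerateTrainingError(AccelpaError):
    """A training set contains fewer than two intensity classes."""


class DesignError(AccelpaError):
    """A cross-validation design cannot be constructed (e.g. one subject)."""


class ConfigError(AccelpaError):
    """A run or generator configuration is invalid."""
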