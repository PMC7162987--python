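"""Package-wide exception types."""


class VibropsychError(Exception):
    """Base class for package errors."""


class InsufficientDataError(VibropsychError, ValueError):
    """An estimator was given too few (or too degenerate) observations."""


class ConfigurationError(VibropsychError, ValueError):
    """A study / observer / battery configuration is inconsistent."""
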