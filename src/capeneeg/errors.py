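"""Exception hierarchy for the C-ApEn EEG pipeline.

Every failure mode the pipeline can diagnose gets its own class so callers
(and tests) can distinguish a malformed montage from a degenerate signal or
an undefined entropy estimate.
"""


class CapenEEGError(Exception):
    """Base class for all package errors."""


class MontageError(CapenEEGError):
    """Recording does not carry the expected 16-channel 10-20 montage."""


class DataError(CapenEEGError):
    """Signal data are unusable (non-finite samples, bad shapes)."""


class DegenerateSignalError(CapenEEGError):
    """A series has zero variance, so it cannot be standardized."""


class UndefinedEntropyError(CapenEEGError):
    """Every template failed to match; the entropy estimate is undefined."""


class MissingFeatureError(CapenEEGError):
    """A required feature cell (pair x condition) is absent."""


class CollinearityError(CapenEEGError):
    """Design matrix is rank deficient; offending columns are reported."""


class DegenerateTableError(CapenEEGError):
    """Contingency table has a zero margin."""


class DegenerateROCError(CapenEEGError):
    """Outcome vector contains a single class; ROC is undefined."""


class CalibrationError(CapenEEGError):
    """Generator knob calibration failed (non-monotone empirical curve)."""


class ConfigError(CapenEEGError):
    """Invalid configuration value."""


class PrerequisiteError(CapenEEGError):
    """A pipeline stage was invoked before its upstream outputs exist."""
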