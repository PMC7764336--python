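"""Exception hierarchy shared across the package."""


class GaitcastError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitcastError):
    """A file or header does not conform to the expected schema."""


class ValidationError(GaitcastError):
    """An input violates a documented precondition or invariant."""


class UnsupportedRateError(GaitcastError):
    """A requested resampling ratio is not an integer decimation."""


class PhaseLabelingError(GaitcastError):
    """Foot-switch events cannot be assembled into a valid gait cycle."""


class UndefinedCorrelationError(GaitcastError):
    """Pearson correlation requested for a constant vector."""


class TrainingDivergedError(GaitcastError):
    """The optimizer produced a non-finite loss."""
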