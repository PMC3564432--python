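"""Exception types raised across the package."""


class SnageError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SnageError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDataError(SnageError, ValueError):
    """Input data are malformed (non-finite samples, wrong shape, ...)."""


class FitDivergedError(SnageError, RuntimeError):
    """The optimizer produced a non-finite cost.

    Carries the last finite parameter vector seen, so a caller can inspect
    where the iteration left the feasible region.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class UndefinedMetricError(SnageError, ValueError):
    """A goodness-of-fit metric is undefined for the given data."""


class ModelFormatError(SnageError, ValueError):
    """A serialized model document is malformed or has the wrong version."""
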