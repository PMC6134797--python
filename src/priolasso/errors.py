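"""Exception hierarchy.

All data-contract violations raise a distinct, named subclass of
:class:`DataValidationError` so callers (and the CLI) can report the precise
problem without string matching.
"""


class PriolassoError(Exception):
    """Base class for all errors raised by this package."""


class DataValidationError(PriolassoError):
    """A dataset, block specification or outcome violates an invariant."""


class UncoveredFeatureError(DataValidationError):
    """A matrix column is not assigned to any block."""


class UnknownFeatureError(DataValidationError):
    """The block specification names a feature absent from the matrix."""


class DuplicateFeatureError(DataValidationError):
    """A feature is assigned to more than one block (or listed twice)."""


class MissingValuesError(DataValidationError):
    """The covariate matrix or outcome contains missing values."""


class NonPositiveTimeError(DataValidationError):
    """A survival time is zero or negative."""


class DegenerateOutcomeError(DataValidationError):
    """Outcome unusable for fitting: constant response, or no events."""


class FeatureMismatchError(PriolassoError):
    """Prediction matrix columns do not match the model's features."""


class NotFittedError(PriolassoError):
    """Operation requires a fitted model."""


class ConvergenceError(PriolassoError):
    """Iterative solver failed to converge within its iteration budget."""
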