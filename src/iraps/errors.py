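"""Exception hierarchy for the iraps package."""


class IrapsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IrapsError, ValueError):
    """A file does not conform to the expected dialect (header, version line, ...)."""


class ParseError(IrapsError, ValueError):
    """A cell could not be parsed; the message carries row/column coordinates."""


class SchemaError(IrapsError, ValueError):
    """A serialized object is missing a required field."""


class DomainError(IrapsError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateInputError(IrapsError, ValueError):
    """Input with no usable spread (e.g. zero variance before z-scoring)."""


class LabelingError(IrapsError, ValueError):
    """A sample lacks a tissue label or carries an unknown one."""


class GroupTooSmallError(IrapsError):
    """A responder/non-responder group is below ``min_group_size``.

    Raised by per-iteration differential expression; the resampling driver
    treats it as an iteration-skip signal, not a failure.
    """


class ConfigurationError(IrapsError, ValueError):
    """A run-level configuration makes every iteration or grid point unusable."""


class ScoringError(IrapsError, ValueError):
    """Too few signature genes overlap the expression matrix to score it."""


class EvaluationError(IrapsError, ValueError):
    """Evaluation is undefined (e.g. a single-class label vector)."""


class OptimizationError(IrapsError):
    """No admissible grid point produced a usable signature.

    Carries the full grid-point table (when available) as ``gridpoints``
    so callers can inspect why each point was skipped.
    """

    def __init__(self, message, gridpoints=None):
        super().__init__(message)
        self.gridpoints = gridpoints


class FittingError(IrapsError, ValueError):
    """A model fit is impossible (too few points) or failed to converge."""
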