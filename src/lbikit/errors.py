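"""Exception hierarchy shared across the package.

All errors derive from :class:`LBIError` so callers can catch the package's
failures with a single handler; data-shaped problems additionally derive from
``ValueError`` to stay idiomatic.
"""


class LBIError(Exception):
    """Base class for every error raised by lbikit."""


class InvalidParameterError(LBIError, ValueError):
    """An optical or model parameter is outside its valid domain."""


class InvalidInputError(LBIError, ValueError):
    """Malformed input data (empty, wrong shape, out of range, NaN)."""


class ShapeError(InvalidInputError):
    """Arrays or images with mismatched dimensions."""


class TruncatedProfileError(InvalidInputError):
    """A radial profile ends before reaching a required intensity threshold."""

    def __init__(self, threshold_fraction: float):
        self.threshold_fraction = threshold_fraction
        super().__init__(
            f"profile never falls below {threshold_fraction:.0%} of its plateau; "
            "cannot extract the corresponding radius"
        )


class FitUnderdeterminedError(InvalidInputError):
    """Too few profile points to constrain the fit."""


class ConvergenceError(LBIError, RuntimeError):
    """Optimizer failed to converge; carries the best result found so far."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class DegenerateFitError(LBIError, ValueError):
    """Discriminant fit is singular or otherwise degenerate."""


class AggregationError(InvalidInputError):
    """A required acquisition position is missing for the requested mode."""


class SamplingError(InvalidInputError):
    """Balanced subsampling is infeasible for the available class counts."""


class VocabularyError(InvalidInputError):
    """A label outside the closed severity vocabulary."""


class AssignmentError(InvalidInputError):
    """A coefficient falls outside every calibration class range."""


class ConfigError(LBIError, ValueError):
    """Run configuration failed schema validation."""
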