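"""Exception hierarchy shared across the package."""


class RumethError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RumethError, ValueError):
    """A numeric or structural parameter violates its contract."""


class InvalidGridError(InvalidParameterError):
    """A time grid is malformed (wrong step, not a multiple of the step, ...)."""


class GridMismatchError(RumethError, ValueError):
    """Two curves that must share a time grid do not."""


class DegenerateDesignError(RumethError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class UnderdeterminedFitError(RumethError, ValueError):
    """Too few distinct observations to identify the model."""


class FitFailureError(RumethError, RuntimeError):
    """Nonlinear fitting failed from every starting point."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidConfigError(RumethError, ValueError):
    """A configuration object violates its invariants."""


class UndefinedStoichiometryError(RumethError, ValueError):
    """VFA stoichiometry requested on an all-zero acid profile."""


class UndefinedRatioError(RumethError, ZeroDivisionError):
    """A VFA ratio has a zero denominator; the message names the ratio."""


class UndefinedProportionError(RumethError, ValueError):
    """Relative abundance requested for a sample with zero total counts."""


class UndefinedDiversityError(RumethError, ValueError):
    """Alpha diversity requested for an all-zero sample."""


class UndefinedDistanceError(RumethError, ValueError):
    """A dissimilarity is undefined (e.g. between two all-zero samples)."""


class InvalidGroupingError(RumethError, ValueError):
    """A grouping for a permutation test has a group with <2 samples."""


class IncompleteBlockError(RumethError, ValueError):
    """A blocked design is missing a cell; the message names the block."""


class UnbalancedDesignError(RumethError, ValueError):
    """A factorial design is not balanced across blocks."""


class PipelineError(RumethError, RuntimeError):
    """A pipeline stage could not run; the message names the stage."""
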