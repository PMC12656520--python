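"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: schema problems exit 2,
data problems exit 3, estimation/convergence problems exit 4.
"""


class SeedHTTError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(SeedHTTError):
    """Input file or configuration does not match the expected schema."""

    exit_code = 2


class DataError(SeedHTTError):
    """Input data violate an invariant (e.g. decreasing cumulative counts)."""

    exit_code = 3


class InsufficientDataError(DataError):
    """Too few usable observations to attempt a fit."""


class ConvergenceError(SeedHTTError):
    """An iterative estimation step failed to converge."""

    exit_code = 4


class NonIdentifiableError(ConvergenceError):
    """The fitted model is degenerate (e.g. non-positive probit slope)."""


class BoundaryWarning(UserWarning):
    """An optimum landed on the edge of its search interval."""
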