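"""Exception hierarchy.

All package errors derive from :class:`ShelfkinError` so callers can catch
one base class at pipeline boundaries.
"""


class ShelfkinError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ShelfkinError):
    """Input file does not conform to the expected tabular layout."""


class ParseError(ShelfkinError):
    """A cell could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateRecordError(ShelfkinError):
    """Two rows describe the same (indicator, temperature, time)."""


class DomainError(ShelfkinError):
    """A value lies outside the mathematical domain of the requested model."""


class InsufficientDataError(ShelfkinError):
    """Fewer usable observations than the operation requires."""


class DegenerateDesignError(ShelfkinError):
    """Regression design matrix is singular (e.g. all times equal)."""


class InputError(ShelfkinError):
    """Inconsistent or empty inputs to an analysis operation."""


class ConfigError(ShelfkinError):
    """Missing or contradictory configuration (unknown indicator, limit...)."""


class ModellingError(ShelfkinError):
    """No feasible model could be produced for the given data."""


class InfeasibleLimitError(ShelfkinError):
    """The critical limit can never be reached under the fitted kinetics."""


class UnsupportedOrderError(ShelfkinError):
    """The reaction order is not supported by this operation."""
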