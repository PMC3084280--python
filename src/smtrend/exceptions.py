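"""Exception hierarchy for smtrend.

All errors raised by the package derive from :class:`SmtrendError` so callers
can catch package failures with a single except clause.
"""


class SmtrendError(Exception):
    """Base class for all smtrend errors."""


class ParseError(SmtrendError):
    """A delimited file contained a value that could not be read as a number."""


class EmptyInputError(SmtrendError):
    """No parseable observations were found in the input."""


class InsufficientDataError(SmtrendError):
    """Too few observations for the requested operation."""


class InvalidPredictorError(SmtrendError):
    """The predictor (time) axis has zero variance; no regression is defined."""


class MethodMismatchError(SmtrendError):
    """An interval-division method was applied to a series it does not support."""


class InvalidDivisionError(SmtrendError):
    """The requested interval count is outside the valid range for the series."""


class SeriesTooShortError(SmtrendError):
    """The series cannot be divided into even the minimum number of intervals."""


class GeneratorRegistryError(SmtrendError, KeyError):
    """No synthetic-series generator is registered under the requested name."""
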