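"""Exception hierarchy shared across the package."""


class SmallAreaError(Exception):
    """Base class for all package-specific errors."""


class SchemeError(SmallAreaError, ValueError):
    """Invalid quasi-identifier scheme, or reference to an unknown variable."""


class ConfigurationError(SmallAreaError, ValueError):
    """Inconsistent configuration (e.g. a declared ethnicity variant is missing)."""


class ParameterError(SmallAreaError, ValueError):
    """A numeric parameter is outside its admissible range."""


class UndefinedResultError(SmallAreaError, ArithmeticError):
    """The requested quantity is undefined for the given input (e.g. empty area)."""


class FittingError(SmallAreaError, RuntimeError):
    """Model fitting cannot proceed (empty class, degenerate design, ...)."""


class DataValidationError(SmallAreaError, ValueError):
    """Malformed input data; the message lists offending rows or values."""


class MissingPopulationError(DataValidationError):
    """Area codes present in the records have no population-table entry."""
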