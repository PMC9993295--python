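"""Exception hierarchy for allodose."""


class AlloDoseError(Exception):
    """Base class for all allodose errors."""


class DomainError(AlloDoseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(AlloDoseError, ValueError):
    """A model, formulary or policy configuration violates its invariants."""


class TableValidationError(ConfigError):
    """A weight-band table violates its structural invariants.

    ``rows`` carries the zero-based indices of the offending bands.
    """

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = tuple(rows)


class CohortValidationError(AlloDoseError, ValueError):
    """A cohort file or specification failed validation.

    ``lines`` carries the one-based line numbers of the offending rows
    when the error originates from a delimited-text file.
    """

    def __init__(self, message: str, lines=()):
        super().__init__(message)
        self.lines = tuple(lines)
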