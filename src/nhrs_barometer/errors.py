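"""Exception hierarchy for the barometer engine."""


class BarometerError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(BarometerError, ValueError):
    """A schema file failed to parse or violated a structural invariant."""


class DomainError(BarometerError, ValueError):
    """An argument fell outside the mathematical domain of an operation."""


class MissingDataError(BarometerError, ValueError):
    """An observation lacks a field an indicator requires.

    Carries ``indicator_id`` and ``country`` so batch pipelines can report
    exactly which cell of the survey table is missing.
    """

    def __init__(self, message: str, *, indicator_id: str = "", country: str = ""):
        super().__init__(message)
        self.indicator_id = indicator_id
        self.country = country


class UnknownColumnError(SchemaError):
    """An observation table contains a column no indicator accounts for."""

    def __init__(self, message: str, *, column: str = ""):
        super().__init__(message)
        self.column = column


class UndefinedChangeError(DomainError):
    """Relative change is undefined because the baseline score is zero."""
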