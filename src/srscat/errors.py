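"""Exception hierarchy.

Everything raised on purpose derives from :class:`SrsCatError` so the CLI can
distinguish user errors (exit 1) from internal faults (exit 2).
"""


class SrsCatError(Exception):
    """Base class for all package errors."""


class CategoryRangeError(SrsCatError, ValueError):
    """A response category lies outside 0..K-1 for the item."""


class DomainError(SrsCatError, ValueError):
    """A numeric argument is outside the function's domain (e.g. non-finite theta)."""


class NumericalUnderflowError(SrsCatError, ArithmeticError):
    """All posterior mass underflowed; the likelihood is numerically zero everywhere."""


class IncompleteAdministrationError(SrsCatError, ValueError):
    """A complete-form score was requested but some items are unanswered."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"incomplete administration; missing items: {self.missing_ids}"
        )


class BankExhaustedError(SrsCatError, RuntimeError):
    """The adaptive engine asked for an item but none remain."""


class UndefinedEffectError(SrsCatError, ZeroDivisionError):
    """An effect size is undefined (zero pooled standard deviation)."""


class ClassMissingError(SrsCatError, ValueError):
    """ROC analysis requires both cases and controls."""


class SchemaError(SrsCatError, ValueError):
    """A tabular input does not conform to the expected schema."""
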