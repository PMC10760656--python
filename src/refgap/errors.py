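"""Exception hierarchy shared across the pipeline."""


class RefgapError(Exception):
    """Base class for all refgap errors."""


class MalformedNameError(RefgapError):
    """A scientific name could not be reduced to a binomial."""


class SchemaError(RefgapError):
    """An input table is missing required columns."""


class ValidationError(RefgapError):
    """An input violates a documented invariant (duplicates, bad enum, ...)."""


class DomainError(RefgapError):
    """An argument is outside the mathematical domain of an operation."""


class UndefinedDenominatorError(DomainError):
    """A percentage was requested with a zero denominator."""


class DegenerateRegionError(RefgapError):
    """A region polygon has zero area or is otherwise unusable."""
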