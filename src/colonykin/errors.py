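"""Exception types shared across the package."""


class ColonykinError(Exception):
    """Base class for all package errors."""


class SchemaError(ColonykinError):
    """A required column is missing or the column mapping is invalid."""


class EmptyInputError(ColonykinError):
    """An input file or record list contains no data rows."""


class ParameterError(ColonykinError, ValueError):
    """A function argument is outside its documented domain."""


class CycleError(ColonykinError):
    """A pedigree contains an individual that is its own ancestor."""

    def __init__(self, chain):
        self.chain = list(chain)
        super().__init__(
            "pedigree cycle detected: " + " -> ".join(str(c) for c in self.chain)
        )


class PedigreeLookupError(ColonykinError, KeyError):
    """An individual ID is not present in the pedigree."""


class UndefinedStatisticError(ColonykinError):
    """A ratio, correlation or comparison is undefined for the given data
    (zero denominator, constant input, too few observations or groups)."""


class DegenerateDesignError(ColonykinError):
    """The model design matrix does not permit estimation (e.g. constant
    covariate, so the slope is inestimable)."""
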