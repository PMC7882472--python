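"""Exception hierarchy shared across the pipeline stages."""


class FragwebError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(FragwebError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(FragwebError):
    """One or more rows violate a value constraint.

    Collects every violation found in a file so a single run reports the
    full set of problems rather than the first one.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class CrossReferenceError(FragwebError):
    """A record refers to an identifier absent from its companion table."""


class DegenerateTransectError(FragwebError):
    """A transect has zero total cover (plants + bare ground + litter)."""


class AllocationError(FragwebError):
    """Abundance cannot be allocated (all matched food-plant covers zero)."""


class EmptyWebError(FragwebError):
    """No consumer survives the exclusion rules for this fragment."""


class StatisticalError(FragwebError):
    """A model fit or averaging step cannot be carried out."""


class RankDeficiencyError(StatisticalError):
    """The design matrix is rank deficient; names the aliased columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased columns: {self.aliased}")
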