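"""Exception types shared across the toolkit."""


class RmcError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(RmcError):
    """An input table is missing a required column or has an invalid value."""


class InputError(RmcError):
    """An argument value violates a precondition."""


class DegenerateFitError(RmcError):
    """A model fit was requested with too few or degenerate data points."""


class ContextLookupError(RmcError):
    """A trinucleotide context / alt / methylation key is absent from the rate table."""


class TrainingError(RmcError):
    """A training set is empty or otherwise unusable."""
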