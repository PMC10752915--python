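"""Exception types shared across the toolkit."""


class DdtcfError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(DdtcfError):
    """An input table does not match its documented schema."""


class ValidationError(DdtcfError):
    """A value violates a domain invariant (counts, ranges, preconditions)."""


class SaturationError(ValidationError):
    """All droplets in a channel are positive: the concentration is unbounded.

    Digital PCR infers concentration from the fraction of *negative*
    partitions; with zero negatives the Poisson estimator diverges and the
    well must be re-run at higher dilution.
    """
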