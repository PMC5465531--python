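"""Exception hierarchy for invalid inputs and statistical degeneracies.

``InvalidInputError`` means the data violate a precondition (empty replicate
list, non-positive measurement) and the computation never starts.
``DegenerateDataError`` means the data parsed fine but the requested
statistic is mathematically undefined on them (constant column for a
correlation, a single-class ROC). ``UndefinedResultError`` is its subclass
for statistics that become undefined only after filtering (e.g. every
change pair falls inside an exclusion zone); callers that want an explicit
"undefined" marker instead of a number catch it.
"""


class HemotrendError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HemotrendError, ValueError):
    """Input data violate a documented precondition."""


class DegenerateDataError(HemotrendError, ValueError):
    """The statistic is undefined on these data (e.g. zero variance)."""


class UndefinedResultError(DegenerateDataError):
    """A filtering rule left no data to compute the statistic from."""


class SchemaError(HemotrendError, ValueError):
    """A CSV input does not match any recognised schema."""
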