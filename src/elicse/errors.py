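"""Exception hierarchy for the elicse package."""


class ElicseError(Exception):
    """Base class for all package errors."""


class SchemaError(ElicseError):
    """A coding scheme is malformed or a log row violates it."""


class IntervalError(ElicseError):
    """An annotation interval is degenerate (stop <= start) or out of range."""


class AlignmentError(ElicseError):
    """Two sequences or coders cannot be paired bin-for-bin or key-for-key."""


class CompletenessError(ElicseError):
    """A participant-session is missing one of the three body-part streams."""


class IntegrityError(ElicseError):
    """Duplicate keys where uniqueness is required."""


class ConditioningError(ElicseError):
    """A covariance matrix is singular or not positive definite."""


class StructureError(ElicseError):
    """A path model violates structural requirements (e.g., cyclic)."""


class OptimizationError(ElicseError):
    """The likelihood optimizer failed to converge."""


class DegeneracyError(ElicseError):
    """A statistic is undefined on this input (zero variance, empty data)."""
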