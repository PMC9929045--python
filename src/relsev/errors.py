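"""Exception hierarchy for relsev.

All package errors derive from :class:`RelsevError` so callers can catch one
base class at pipeline boundaries.
"""


class RelsevError(Exception):
    """Base class for all relsev errors."""


class SchemaError(RelsevError):
    """A required column cannot be resolved in an input table."""


class IntegrityError(RelsevError):
    """Duplicate or contradictory measurements in an input table."""


class BaselineError(RelsevError):
    """Baseline value absent, zero, or otherwise unusable for standardization."""


class DegenerateReferenceError(RelsevError):
    """A reference variable shows no adverse deviation; its scaling denominator
    would be zero."""


class IncompatibleReferenceError(RelsevError):
    """Reference set and test data share no usable variables."""


class EmptyCurveError(RelsevError):
    """A severity curve has no non-missing days."""


class SampleSizeError(RelsevError):
    """Too few observations for the requested estimator or test."""
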