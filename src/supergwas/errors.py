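"""Exception hierarchy for supergwas.

Every error raised by the library derives from :class:`SuperGwasError`, so
callers (and the CLI) can catch one base class.  Subclasses map onto the
failure modes of the pipeline stages: parsing, validation, alignment,
degenerate model fits, and degenerate kinships.
"""


class SuperGwasError(Exception):
    """Base class for all supergwas errors."""


class ParseError(SuperGwasError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(SuperGwasError):
    """Input data violates a documented invariant (e.g. dosage outside [0, 2])."""


class DimensionError(SuperGwasError):
    """Matrix / vector dimensions do not agree."""


class AlignmentError(SuperGwasError):
    """Sample identifiers of two tables cannot be aligned (empty intersection)."""


class EmptyResultError(SuperGwasError):
    """A filter removed every marker; the message reports per-filter counts."""


class DegenerateKinshipError(SuperGwasError):
    """All markers requested for a kinship are monomorphic (normalizer = 0)."""


class EmptyKinshipError(SuperGwasError):
    """A marker-exclusion emptied the kinship's marker set.

    Callers performing per-marker exclusion treat this as a signal to fall
    back to a fixed-effects-only (GLM) test rather than as a hard failure.
    """


class DegenerateFitError(SuperGwasError):
    """The trait has no residual variance left for the model to explain."""


class SelectionError(SuperGwasError):
    """Pseudo-QTN selection found no testable marker."""


class OptimizationError(SuperGwasError):
    """Every (s, b) cell of a bin-optimization grid was degenerate."""


class ParameterError(SuperGwasError):
    """A user-supplied parameter is outside its documented range."""
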