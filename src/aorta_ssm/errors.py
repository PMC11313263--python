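"""Exception hierarchy for the aorta shape-analysis pipeline.

Every error raised deliberately by this package derives from
:class:`AortaSSMError`, so callers can distinguish contract violations
from genuine bugs.
"""


class AortaSSMError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AortaSSMError, ValueError):
    """A geometric or cohort parameter violates its stated domain."""


class MeshFormatError(AortaSSMError, ValueError):
    """A mesh file is malformed (bad header, truncated body, ...)."""


class MeshGeometryError(AortaSSMError, ValueError):
    """A mesh violates a geometric precondition (open boundary, bad loop)."""


class CorrespondenceError(AortaSSMError, ValueError):
    """Point sets that must be in correspondence are not."""


class UndefinedCorrelationError(AortaSSMError, ValueError):
    """Correlation distance requested for a zero-variance vector."""


class DegenerateTableError(AortaSSMError, ValueError):
    """A contingency table has a zero margin and no valid chi-squared test."""


class CollinearityError(AortaSSMError, ValueError):
    """Design matrix is rank deficient."""


class UndefinedTortuosityError(AortaSSMError, ValueError):
    """Tortuosity requested for a centreline with coincident endpoints."""
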