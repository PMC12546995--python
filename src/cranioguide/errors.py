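"""Exception hierarchy.

``ValueError`` subclasses signal invalid caller input; ``RuntimeError``
subclasses signal geometric or numerical conditions discovered while
computing (a ray that misses the scalp, a rank-deficient solve).
"""


class CranioGuideError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CranioGuideError, ValueError):
    """A precondition on caller-supplied data is violated."""


class SchemaError(InvalidInputError):
    """A file does not match its declared schema; names the offending field."""


class RayMissError(CranioGuideError, RuntimeError):
    """A cast ray does not intersect the surface."""


class ContourError(CranioGuideError, RuntimeError):
    """A plane cut or arc extraction could not be completed."""


class DegeneracyError(CranioGuideError, RuntimeError):
    """A fit or construction is numerically degenerate (rank deficiency)."""


class LayoutError(CranioGuideError, RuntimeError):
    """A 10-20 layout construction step failed; message names the arc."""
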