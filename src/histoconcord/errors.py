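"""Exception hierarchy for the concordance pipeline.

Every error a caller may want to catch selectively has its own class;
all inherit from :class:`HistoconcordError` so a CLI can catch one type.
"""


class HistoconcordError(Exception):
    """Base class for all package errors."""


class FormatError(HistoconcordError):
    """Input file is not in the expected format (e.g. not a 3D volume)."""


class OrientationError(HistoconcordError):
    """Image affine is oblique beyond tolerance; axes cannot be mapped to
    anatomical directions."""


class GridMismatchError(HistoconcordError):
    """Two masks that must share a voxel grid do not."""


class ExtentError(HistoconcordError):
    """Geometry (contour, ellipsoid) does not fit inside the voxel grid."""


class ContractError(HistoconcordError):
    """A documented precondition was violated (e.g. an untrimmed GTV passed
    to segment scoring)."""


class DegenerateAnatomyError(HistoconcordError):
    """Gland too small for the requested partition (fewer than 3 axial
    slices contain gland voxels)."""


class UndefinedMetricError(HistoconcordError):
    """A metric has no defined value for the given input (e.g. DSC of two
    empty masks)."""


class PhantomSpecError(HistoconcordError):
    """Synthetic phantom specification is inconsistent (lesion outside
    gland, ellipsoid outside grid, ...)."""
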