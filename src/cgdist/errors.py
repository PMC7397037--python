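"""Exception hierarchy for the cgdist pipeline.

Every stage raises a subclass of :class:`CgdistError`, so callers (batch
drivers, the CLI) can catch pipeline failures without swallowing
programming errors.
"""


class CgdistError(Exception):
    """Base class for all cgdist pipeline errors."""


class UnsupportedFormatError(CgdistError):
    """Input image is not a single-plane grayscale raster."""


class CalibrationError(CgdistError):
    """Pixel size is unavailable from metadata and no override was given."""


class ValidationError(CgdistError):
    """A record or table violates its contract (NaN, bad column, bad value)."""


class SchemaError(ValidationError):
    """A table is missing required columns."""


class GeometryError(CgdistError):
    """A geometric construction is infeasible (oocyte outside frame,
    windows that cannot be placed, ...)."""


class SegmentationError(CgdistError):
    """Ooplasm segmentation failed to produce an acceptable mask."""


class DegenerateInputError(CgdistError):
    """Input carries no usable signal (e.g. constant image)."""


class CongruenceError(CgdistError):
    """Two grids that must be congruent have different shapes."""


class PartitionInfeasibleError(CgdistError):
    """The requested central area fraction cannot be achieved within
    tolerance on this mask."""

    def __init__(self, message: str, best_fraction: float | None = None):
        super().__init__(message)
        self.best_fraction = best_fraction


class UndefinedIndexError(CgdistError):
    """I_cgd is undefined (zero central mean)."""


class ResolutionError(CgdistError):
    """Pixel size too coarse to resolve the requested spot scale."""


class InsufficientDataError(CgdistError):
    """A statistical comparison was requested with too few observations."""


class DegenerateDataError(CgdistError):
    """The test statistic is undefined (zero variance in both groups with
    equal means)."""
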