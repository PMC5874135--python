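"""Exception hierarchy for seedpls.

All package errors derive from :class:`SeedPLSError` so callers can catch one
base class; the subclasses mirror the distinct failure contracts of the
pipeline stages.
"""


class SeedPLSError(Exception):
    """Base class for all seedpls errors."""


class InvalidConfigError(SeedPLSError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateDataError(SeedPLSError, ValueError):
    """Requested data would carry no variation (e.g. zero noise, no patterns)."""


class DegenerateVarianceError(SeedPLSError, ValueError):
    """A voxel column or seed vector has zero variance within an age group."""

    def __init__(self, message, group=None, column=None):
        super().__init__(message)
        self.group = group
        self.column = column


class MidlineSeedError(SeedPLSError, ValueError):
    """Attempt to mirror a midline (x == 0) seed."""


class OutOfBoundsError(SeedPLSError, ValueError):
    """A world coordinate maps outside the voxel grid."""


class UnsupportedAffineError(SeedPLSError, ValueError):
    """Affine is not an axis-aligned scaling plus translation."""


class EmptyROIError(SeedPLSError, ValueError):
    """A cubical ROI does not intersect the analysis mask."""


class AgeOutOfRangeError(SeedPLSError, ValueError):
    """An age falls outside the age-group scheme coverage."""


class DatasetError(SeedPLSError, ValueError):
    """Dataset on disk is inconsistent (missing volume, grid mismatch, ...)."""
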