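"""Exception types raised across the package."""


class VoronoiTrackError(Exception):
    """Base class for all package-specific errors."""


class CenterlineParseError(VoronoiTrackError):
    """A centerline text file contains a malformed line."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class InvalidCenterlineError(VoronoiTrackError):
    """A centerline violates its invariants (too short, non-positive radii, ...)."""


class UnsupportedOrientationError(VoronoiTrackError):
    """A NIfTI affine is not axis-aligned with positive isotropic scales."""


class OutOfBoundsError(VoronoiTrackError):
    """A millimetre coordinate maps outside the voxel grid."""


class PhantomError(VoronoiTrackError):
    """Phantom parameters would produce a self-intersecting tube."""


class SizeLimitError(VoronoiTrackError):
    """A requested voxel grid exceeds the configured voxel budget."""


class EmptyExtractionError(VoronoiTrackError):
    """Centerline extraction produced no usable points."""
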