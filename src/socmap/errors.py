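"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`SocmapError` so drivers can catch
pipeline failures without masking programming errors.
"""


class SocmapError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(SocmapError, ValueError):
    """Input violates a declared bound or structural requirement."""


class GeometryError(SocmapError):
    """Image grids or affines do not match."""


class AlignmentError(SocmapError):
    """Time axes or track lengths do not line up."""


class CompletenessError(SocmapError):
    """A required clip, feature or map is missing."""


class CollinearityError(SocmapError):
    """Design columns are rank deficient."""

    def __init__(self, message, dependent=()):
        super().__init__(message)
        self.dependent = tuple(dependent)


class DegenerateDataError(SocmapError):
    """Zero-variance data where a correlation or t statistic is required."""


class EmptyRoiError(SocmapError):
    """A spherical ROI contains no in-mask voxels."""


class PairingError(SocmapError):
    """Subjects in two map sets cannot be paired."""


class SaturationError(SocmapError):
    """|r| = 1 where the Fisher transform is undefined."""
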