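"""Exception hierarchy for warpgauge.

Every anticipated failure mode of the pipeline maps to one subclass of
:class:`WarpgaugeError`, so callers can catch pipeline problems without
swallowing programming errors.
"""


class WarpgaugeError(Exception):
    """Base class for all warpgauge errors."""


class InvalidSpecError(WarpgaugeError):
    """A phantom or distortion specification violates its invariants."""


class NoSignalError(WarpgaugeError):
    """An input volume carries no usable signal (all zero / empty mask)."""


class OverlapError(WarpgaugeError):
    """Too few voxels overlap between fixed and mapped moving volumes.

    Usually signals a diverged transform during registration.
    """


class SingularTransformError(WarpgaugeError):
    """A transform matrix is singular and cannot be inverted."""


class ReflectionError(WarpgaugeError):
    """An affine has negative determinant; registration produced a reflection."""


class DegenerateInputError(WarpgaugeError):
    """A similarity measure received degenerate input (e.g. constant image)."""


class GridError(WarpgaugeError):
    """Two volumes expected on the same grid are not."""


class ParcellationError(WarpgaugeError):
    """The brain mask cannot be split into the requested regions."""


class EmptyMatchError(WarpgaugeError):
    """No landmark names are shared between two landmark sets."""


class OutOfBoundsError(WarpgaugeError):
    """A requested sub-volume lies outside its parent volume."""


class UnsupportedFormatError(WarpgaugeError):
    """An input file is not a 3D scalar NIfTI volume."""


class EmptySummaryError(WarpgaugeError):
    """Every region was excluded; there is nothing to summarize."""
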