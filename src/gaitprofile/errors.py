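"""Exception hierarchy for the gait pipeline.

Every stage fails loudly with a typed error naming the offending input;
no stage silently repairs or skips data.
"""


class GaitProfileError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitProfileError):
    """A model/pipeline configuration is invalid (e.g. missing marker label)."""


class ValidationError(GaitProfileError):
    """An input violates a documented precondition."""


class GeometryError(GaitProfileError):
    """Degenerate marker geometry (collinear points, zero breadth, ...)."""


class GapError(GaitProfileError):
    """A marker sample is missing and gap filling is disabled."""


class SolvabilityError(GaitProfileError):
    """An inverse-kinematics frame is under-determined or failed to solve."""


class ResolutionError(GaitProfileError):
    """A permutation test cannot resolve the requested significance level."""
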