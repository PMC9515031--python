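"""Exception hierarchy for the cartilage analysis pipeline.

Exit-code mapping used by the CLI: input problems (format, dimensionality,
parameters, alignment) map to exit code 2; degenerate geometry (sphere fit,
frame construction, localization failures) to exit code 3.
"""


class HipcartError(Exception):
    """Base class for all package errors."""


class FormatError(HipcartError):
    """File is unreadable or not in a supported format."""


class DimensionalityError(FormatError):
    """Input volume is not a 3D scalar grid."""


class ParameterError(HipcartError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class AlignmentError(HipcartError):
    """Two volumes that must share geometry do not."""


class DomainError(HipcartError):
    """Input data violates an operation's precondition (e.g. empty mask)."""


class GeometryError(HipcartError):
    """Degenerate geometric configuration."""


class FitError(GeometryError):
    """Sphere fit impossible (too few or coplanar points)."""


class AmbiguityError(GeometryError):
    """Principal-axis direction is not uniquely defined."""


class FrameError(GeometryError):
    """Anatomical frame construction is degenerate."""


class LocalizationError(GeometryError):
    """Femoral-head localization produced no usable maximum."""


class PipelineError(HipcartError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
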