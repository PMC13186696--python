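"""Exception hierarchy.

Every error raised by the package derives from :class:`GlycoAtlasError`, so
callers can catch one type at pipeline level while stages raise precise
subclasses.
"""


class GlycoAtlasError(Exception):
    """Base class for all package errors."""


class FormatError(GlycoAtlasError):
    """A localization table or sidecar file violates the expected format."""


class ParameterError(GlycoAtlasError):
    """An operation received an out-of-range or inconsistent parameter."""


class GeometryError(GlycoAtlasError):
    """A polygon ROI is degenerate (self-intersecting, zero area, < 3 vertices)."""


class InsufficientDataError(GlycoAtlasError):
    """Not enough data to run an estimator (e.g. < 2 occupied frames)."""


class EstimationError(GlycoAtlasError):
    """A fit failed to converge; carries diagnostics for the caller."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DriftUnavailableError(GlycoAtlasError):
    """No fiducial tracks available, drift correction cannot be estimated."""


class AlignmentError(GlycoAtlasError):
    """Too few matched fiducials for the requested channel alignment."""


class UndefinedPairError(GlycoAtlasError):
    """A nearest-neighbour query has no valid target (empty or singleton set)."""


class EmptyHistogramError(GlycoAtlasError):
    """All distances fall outside the histogram range."""


class SchemaError(GlycoAtlasError):
    """Samples entering feature assembly have inconsistent channel panels."""


class SceneSpecError(GlycoAtlasError):
    """A synthetic scene specification is internally inconsistent."""


class PipelineStageError(GlycoAtlasError):
    """A pipeline stage failed; names the stage and preserves the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
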