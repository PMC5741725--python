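"""Exception hierarchy shared across the package."""


class ProsthofaceError(Exception):
    """Base class for all package-specific errors."""


class MeshValidationError(ProsthofaceError):
    """Mesh violates a structural invariant (bad indices, degenerate faces...)."""


class ObjParseError(ProsthofaceError):
    """Malformed Wavefront OBJ input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class LandmarkSchemaError(ProsthofaceError):
    """Landmark file is missing a required key or carries malformed values."""


class DegenerateGeometryError(ProsthofaceError):
    """Geometric configuration is rank-deficient (collinear landmarks etc.)."""


class RegionError(ProsthofaceError):
    """A region mask is empty or inconsistent with its mesh."""


class IsolineError(ProsthofaceError):
    """Iso-plane does not intersect the mesh, or the polyline is too short."""


class DetectionError(ProsthofaceError):
    """Fewer curvature extrema than requested feature points."""

    def __init__(self, message: str, found: int = 0, requested: int = 0):
        self.found = found
        self.requested = requested
        super().__init__(message)


class TemplateError(ProsthofaceError):
    """Feature-template construction failed; names the step that failed."""

    def __init__(self, message: str, step: int | None = None):
        self.step = step
        if step is not None:
            message = f"step {step}: {message}"
        super().__init__(message)


class SolvabilityError(ProsthofaceError):
    """Constrained Laplacian system is rank deficient."""


class ConstraintConflictError(ProsthofaceError):
    """Control and anchor constraint sets overlap."""


class DivergenceError(ProsthofaceError):
    """Network training produced a non-finite loss; carries the epoch."""

    def __init__(self, message: str, epoch: int | None = None):
        self.epoch = epoch
        if epoch is not None:
            message = f"epoch {epoch}: {message}"
        super().__init__(message)


class ParameterError(ProsthofaceError):
    """Synthetic-generator parameters are out of their valid range."""


class PipelineError(ProsthofaceError):
    """An end-to-end pipeline stage failed; names subject and stage."""

    def __init__(self, message: str, subject: str | None = None, stage: str | None = None):
        self.subject = subject
        self.stage = stage
        prefix = " ".join(p for p in (subject, stage) if p)
        super().__init__(f"[{prefix}] {message}" if prefix else message)
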