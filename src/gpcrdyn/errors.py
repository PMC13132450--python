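"""Exception hierarchy shared by all gpcrdyn modules."""


class GpcrDynError(Exception):
    """Base class for all package errors."""


class FormatError(GpcrDynError):
    """Unparseable record in an input file (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RoleAssignmentError(GpcrDynError):
    """A chain in the input has no entry in the chain -> role table."""


class TopologyError(GpcrDynError):
    """Trajectory/selection is inconsistent with the topology (atom counts, missing atoms)."""


class TruncationError(GpcrDynError):
    """Trajectory container ended mid-frame; carries the last intact frame index."""

    def __init__(self, message: str, last_good_frame: int):
        self.last_good_frame = last_good_frame
        super().__init__(f"{message} (last intact frame: {last_good_frame})")


class SelectionError(GpcrDynError):
    """A selection that must be non-empty resolved to no atoms."""


class MappingError(GpcrDynError):
    """A generic residue label cannot be resolved against the numbering map."""


class SpecError(GpcrDynError):
    """A generator/analysis specification is internally inconsistent or unachievable."""


class GeometryError(GpcrDynError):
    """Degenerate geometry (coincident/collinear points) where an angle is undefined."""


class LookupError_(GpcrDynError):
    """Requested residue absent from the topology."""


class ClassificationError(GpcrDynError):
    """A metric required by the state reference is missing from the input."""


class GraphError(GpcrDynError):
    """Ligand bond graph violates a structural precondition (e.g. disconnected)."""


class NoPathError(GpcrDynError):
    """Source and sink lie in different connected components of the residue graph."""


class CommunityError(GpcrDynError):
    """Community detection requested on an edgeless graph."""


class OverlapError(GpcrDynError):
    """Adjacent umbrella windows share no sampled histogram bins."""


class ConvergenceError(GpcrDynError):
    """Self-consistent iteration failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class ConsistencyError(GpcrDynError):
    """Hills records mix incompatible parameters (bias factor, units)."""


class DegeneratePathError(GpcrDynError):
    """Path extraction requested with identical start and end nodes."""


class DegenerateDensityError(GpcrDynError):
    """Kernel density requested for data with zero variance in every dimension."""
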