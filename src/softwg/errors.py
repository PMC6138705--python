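"""Exception hierarchy shared across the package."""


class SoftwgError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SoftwgError):
    """A run configuration or grid specification is invalid."""


class ResolutionError(ConfigurationError):
    """The grid is too coarse to resolve a geometric feature."""


class DomainError(SoftwgError):
    """Geometry or a requested evaluation point lies outside the valid domain."""


class PlacementError(SoftwgError):
    """A source or probe falls outside the usable (non-PML) interior."""


class InstabilityError(SoftwgError):
    """Non-finite fields were detected during time stepping."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite field detected at step {step}")


class AnalysisError(SoftwgError):
    """An analysis precondition failed (empty window, degenerate data, ...)."""


class DegenerateReferenceError(AnalysisError):
    """The reference trace has no peak-to-peak span."""
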