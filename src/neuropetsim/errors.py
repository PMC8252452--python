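"""Exception hierarchy for the toolkit."""


class NeuroPETSimError(Exception):
    """Base class for all package errors."""


class GeometryError(NeuroPETSimError):
    """Volumes/sinograms live on incompatible grids, or an object leaves the FOV."""


class SemanticsError(NeuroPETSimError):
    """A volume carries the wrong semantic role for the requested operation."""


class InvalidSpecError(NeuroPETSimError):
    """A phantom, scanner or config specification violates its invariants."""


class UnsupportedOrientationError(NeuroPETSimError):
    """NIfTI affine is oblique; only axis-aligned (up to flips) grids are handled."""


class EmptySourceError(NeuroPETSimError):
    """Activity map contains no activity; nothing can be simulated."""


class UndefinedCorrelationError(NeuroPETSimError):
    """Pearson correlation is undefined (zero variance within the mask)."""
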