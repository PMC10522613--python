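"""Exception hierarchy for the tribs pipeline.

Every stage raises a subclass of :class:`TribsError` so callers can catch
pipeline failures without masking programming errors.
"""


class TribsError(Exception):
    """Base class for all tribs errors."""


class InvalidModelError(TribsError):
    """Limb model parameters are unusable (e.g. non-positive segment length)."""


class FrameTagError(TribsError):
    """An operation mixed points expressed in different coordinate frames."""


class SolverError(TribsError):
    """A numeric solver failed to meet its residual contract."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InconsistentMarkerError(TribsError):
    """Marker geometry contradicts the limb model (e.g. wrong clavicle length)."""


class GeometryError(TribsError):
    """Degenerate or impossible geometry for the requested construction."""


class MissingMarkerError(TribsError):
    """A required marker is absent from the input frame."""


class ConfigError(TribsError):
    """Invalid run configuration."""
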