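"""Exception hierarchy.

Every failure mode that callers are expected to handle gets its own class so
the CLI can map them to distinct exit messages; all inherit from
:class:`CraniometricsError`.
"""


class CraniometricsError(Exception):
    """Base class for all package-specific errors."""


class IncompleteLandmarkError(CraniometricsError):
    """A required landmark is missing ("incomplete landmark set")."""


class DegenerateFrameError(CraniometricsError):
    """Frame-defining points are collinear or coincident ("degenerate frame")."""


class OpenMeshError(CraniometricsError):
    """Mesh is not watertight ("open mesh")."""


class MeshReadError(CraniometricsError):
    """Mesh file could not be parsed at all (distinct from topology errors)."""


class ShortMeshError(CraniometricsError):
    """Mesh does not reach a required slicing height ("short mesh")."""


class ContourError(CraniometricsError):
    """Cross-section contour missing, multiple, or degenerate."""


class EmptyQuadrantError(CraniometricsError):
    """A quadrant volume is zero where a ratio is requested ("empty quadrant")."""


class CalibrationError(CraniometricsError):
    """Preset calibration could not satisfy the requested targets."""


class ValidationError(CraniometricsError):
    """Generic input validation failure (bad probability, bad scale pair, ...)."""


class CollinearDesignError(CraniometricsError):
    """Regression design matrix is rank-deficient ("collinear design")."""
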