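"""Exception hierarchy for the ablaquant pipeline."""


class AblaquantError(Exception):
    """Base class for all package errors."""


class FormatError(AblaquantError):
    """A file or in-memory object violates an expected format."""


class GeometryError(AblaquantError):
    """Inconsistent or invalid spatial specification (grids, organs, sites)."""


class MeshError(AblaquantError):
    """Mesh construction or query failure."""


class AssemblyError(AblaquantError):
    """Finite-element assembly failure (e.g. inverted element)."""


class SolverError(AblaquantError):
    """Iterative or direct linear solve failed."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class ConstraintError(AblaquantError):
    """Dirichlet/hanging-node constraint set is inconsistent or singular."""


class CorrespondenceError(AblaquantError):
    """Surface correspondence could not be established."""


class RegistrationError(AblaquantError):
    """Linear registration failure (e.g. no initial overlap)."""


class CalibrationError(AblaquantError):
    """Force-scale calibration could not bracket or reach the target."""


class PipelineError(AblaquantError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
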