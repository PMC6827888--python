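"""Exception hierarchy shared across the package."""


class CytoconvectError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CytoconvectError, ValueError):
    """A caller-supplied value violates a documented precondition."""


class GeometryError(CytoconvectError, ValueError):
    """A geometric descriptor is infeasible (e.g. nucleus touches the membrane)."""


class MeshingError(CytoconvectError, RuntimeError):
    """Mesh generation produced (or would produce) a degenerate mesh."""


class ConfigurationError(CytoconvectError, ValueError):
    """Inconsistent combination of mesh, fields or solver settings."""


class ConvergenceError(CytoconvectError, RuntimeError):
    """Iterative solve failed to reach the residual tolerance.

    Carries the residual history so the failure is diagnosable.
    """

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
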