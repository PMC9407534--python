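"""Exception hierarchy shared across the package."""


class GelshellError(Exception):
    """Base class for all package errors."""


class MeshFormatError(GelshellError):
    """A mesh file could not be parsed as the declared format."""


class TopologyError(GelshellError):
    """Mesh connectivity violates the manifold-with-boundary contract."""


class GeometryError(GelshellError):
    """Degenerate or otherwise unusable element geometry."""


class DimensionError(GelshellError):
    """Array sizes do not match mesh entity counts."""


class MeshingError(GelshellError):
    """A parametric generator could not realize the requested geometry."""


class InvertedElementError(GelshellError):
    """det F <= 0 for some element."""

    def __init__(self, message, element=None):
        super().__init__(message)
        self.element = element


class RootBracketError(GelshellError):
    """Plane-stress thickness-stretch root could not be bracketed."""


class AssemblyError(GelshellError):
    """Non-finite entries while assembling a linear system."""


class LinearSolveError(GelshellError):
    """Sparse linear solve failed or left a large residual."""


class StepError(GelshellError):
    """A quasi-static load step failed to converge."""


class ConfigError(GelshellError):
    """Configuration failed schema validation; carries all messages."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
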