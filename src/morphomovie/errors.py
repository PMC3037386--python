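"""Exception hierarchy shared across the package."""


class MorphoMovieError(Exception):
    """Base class for all package errors."""


class ParameterError(MorphoMovieError, ValueError):
    """Invalid configuration or operation parameter."""


class GeometryError(MorphoMovieError):
    """Degenerate or inconsistent geometry (self-intersection, zero area...)."""


class MeshError(MorphoMovieError):
    """Mesh topology violation (non-manifold edge, disconnected mesh...)."""


class ConsistencyError(MorphoMovieError):
    """Cross-object mismatch (mesh vs shape, map vs field sizes...)."""


class MappingError(MorphoMovieError):
    """Boundary-mapping failure (spline intersection counts differ...)."""


class ConvergenceError(MorphoMovieError):
    """Iterative solver failed to reach its tolerance."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class DeformationError(MorphoMovieError):
    """Mesh element inversion during deformation."""


class StabilityError(MorphoMovieError):
    """Explicit time step violates the stability bound."""

    def __init__(self, message, suggested_substeps=None):
        super().__init__(message)
        self.suggested_substeps = suggested_substeps
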