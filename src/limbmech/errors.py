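"""Exception hierarchy shared across the pipeline."""


class LimbmechError(Exception):
    """Base class for all pipeline errors."""


class MeshNotClosedError(LimbmechError):
    """Raised when a volume/inertia operation receives an open mesh."""

    def __init__(self, n_boundary_edges: int, name: str = "mesh"):
        self.n_boundary_edges = n_boundary_edges
        super().__init__(
            f"{name} not closed: {n_boundary_edges} boundary edge(s) "
            "(every edge must be shared by exactly two faces)"
        )


class DegenerateGeometryError(LimbmechError):
    """Raised for degenerate point configurations (coplanar, collinear...)."""


class ModelConfigError(LimbmechError):
    """Raised when a model definition is inconsistent (cycles, missing segments...)."""


class PathResolutionError(LimbmechError):
    """Raised when a musculotendon path cannot be resolved at a pose."""
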