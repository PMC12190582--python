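"""Exception types shared across the simulation pipeline."""


class ResolutionError(ValueError):
    """Grid or mesh resolution below the documented floor."""


class GeometryError(ValueError):
    """Degenerate or self-intersecting contour / domain geometry."""


class ElementInversionError(RuntimeError):
    """A solid triangle reached non-positive area (J <= 0)."""

    def __init__(self, triangle_index: int, message: str | None = None):
        self.triangle_index = int(triangle_index)
        super().__init__(message or f"element inversion in triangle {triangle_index}")


class NodeEscapeError(RuntimeError):
    """A Lagrangian node left the fluid domain (kernel support broken)."""

    def __init__(self, node_index: int, message: str | None = None):
        self.node_index = int(node_index)
        super().__init__(message or f"node {node_index} escaped the fluid domain")


class TimeStepError(RuntimeError):
    """Requested time step violates a stability bound."""


class SolverDivergenceError(RuntimeError):
    """NaN/Inf detected in the fields during time stepping."""

    def __init__(self, step: int, message: str | None = None):
        self.step = int(step)
        super().__init__(message or f"non-finite field values at step {step}")


class TransitTimeoutWarning(UserWarning):
    """max_time reached before the cell passed the exit station."""
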