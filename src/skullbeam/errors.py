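"""Exception hierarchy for skullbeam."""


class SkullbeamError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SkullbeamError, ValueError):
    """A scene element does not fit the simulation domain or is ill-posed."""


class DomainError(SkullbeamError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigError(SkullbeamError, ValueError):
    """A configuration file or solver setting is invalid.

    Carries ``field`` naming the offending configuration entry when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message if field is None else f"{field}: {message}")
        self.field = field


class SolverDivergenceError(SkullbeamError, RuntimeError):
    """The time integration produced non-finite fields.

    ``step`` records the first time step at which divergence was detected.
    """

    def __init__(self, step: int):
        super().__init__(f"non-finite pressure field detected at step {step}")
        self.step = step


class OutOfRangeError(SkullbeamError, ValueError):
    """A query point lies outside the sampled parameter hull."""


class InvalidRegionError(SkullbeamError, ValueError):
    """A query falls in a cell with at least one invalid (unsimulated) corner,
    e.g. the theoretical focus sits inside bone or outside the head."""


class DegenerateSimulationError(SkullbeamError, ValueError):
    """A simulation produced a degenerate result (e.g. zero water peak)."""


class AccuracyError(SkullbeamError, ValueError):
    """A numerical discretization is too coarse for the requested accuracy."""
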