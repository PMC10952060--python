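"""Exception hierarchy shared across the package.

All errors derive from :class:`LoxtrajError` so callers can catch the
package's failures with one clause; the subclasses distinguish malformed
input files, bad selections, degenerate geometry, and configuration
mistakes.
"""


class LoxtrajError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LoxtrajError, ValueError):
    """A structure or trajectory file violates its declared format."""


class ShapeError(LoxtrajError, ValueError):
    """Array or frame shapes are inconsistent (e.g. atom-count mismatch)."""


class SelectionError(LoxtrajError, ValueError):
    """A selection expression failed to parse or resolve.

    Carries the character ``position`` of the offending token when the
    failure is syntactic.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class CardinalityError(LoxtrajError, ValueError):
    """A selection resolved to the wrong number of atoms."""


class GeometryError(LoxtrajError, ValueError):
    """Degenerate geometry: coincident centers, collinear point sets, ..."""


class ConfigurationError(LoxtrajError, ValueError):
    """Invalid parameter values or pipeline configuration."""


class SpecError(LoxtrajError, ValueError):
    """A synthetic-complex specification is infeasible."""


class SeedBuriedError(LoxtrajError, RuntimeError):
    """The tunnel seed voxel has clearance below the probe radius."""


class NoTunnelError(LoxtrajError, RuntimeError):
    """No path with clearance >= probe connects the seed to the surface."""


class SingularityError(LoxtrajError, ValueError):
    """An electrostatic evaluation point coincides with a charge site."""
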