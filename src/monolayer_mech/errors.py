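"""Typed exceptions shared across the package."""


class MonolayerMechError(Exception):
    """Base class for all package-specific errors."""


class DegenerateFieldError(MonolayerMechError):
    """Velocity field has no usable signal (all-zero vectors, zero variance, empty mask)."""


class UnresolvableCorrelationError(MonolayerMechError):
    """Requested correlation length is below the grid spacing."""


class GeometryError(MonolayerMechError):
    """Invalid or singular shell/polygon geometry."""


class ShapeSolverError(MonolayerMechError):
    """The constant-volume shape solver failed to converge or was given an
    indentation outside the solvable range."""


class FormatError(MonolayerMechError):
    """A file did not match the documented schema."""


class UnitMismatchError(FormatError):
    """Declared units in a file header differ from the expected ones."""
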