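"""Exception hierarchy shared across the pipeline stages."""


class CortvowelError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(CortvowelError, ValueError):
    """A configuration value violates a precondition (bad ratio, empty design, ...)."""


class InvalidInputError(CortvowelError, ValueError):
    """Input data violate a contract (mismatched shapes, unknown labels, ...)."""


class DegenerateGeometryError(CortvowelError, ValueError):
    """Sensor/source geometry is degenerate (sensor coincides with a dipole)."""


class NoSourceError(CortvowelError, ValueError):
    """No source vertices are available for estimation (empty area prior)."""


class NumericalError(CortvowelError, ArithmeticError):
    """A linear system turned out singular / non-positive-definite."""


class BundleError(CortvowelError, OSError):
    """An HDF5 bundle is unreadable, truncated or version-incompatible."""
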