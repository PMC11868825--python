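"""Exception types used across the package."""


class QDIError(Exception):
    """Base class for package-specific errors."""


class InsufficientDataError(QDIError, ValueError):
    """Not enough usable data points/directions for the requested operation."""


class ConvergenceError(QDIError, RuntimeError):
    """A series or iterative scheme failed to converge."""


class IPTableRangeError(QDIError, ValueError):
    """Query parameters fall outside the lookup-table grid."""


class GeometryError(QDIError, ValueError):
    """Image/scheme/mask shapes are inconsistent."""
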