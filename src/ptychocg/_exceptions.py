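"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`PtychoError`, so callers can catch one type at tool boundaries.
"""


class PtychoError(Exception):
    """Base class for all errors raised by ptychocg."""


class GeometryError(PtychoError, ValueError):
    """Scan position / probe / object shapes are mutually inconsistent."""


class DataError(PtychoError, ValueError):
    """Measured data violates a physical precondition (e.g. negative counts)."""


class ConfigurationError(PtychoError, ValueError):
    """A configuration value is out of its admissible range or infeasible."""


class ProtocolError(PtychoError, RuntimeError):
    """The partitioned-solver stage protocol was violated (stale halo,
    missing worker block, inconsistent neighbor links, coverage gap)."""


class NumericError(PtychoError, ArithmeticError):
    """A reduction produced a non-finite value."""


class FormatError(PtychoError, ValueError):
    """A persisted dataset file is malformed or has an unknown version."""
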