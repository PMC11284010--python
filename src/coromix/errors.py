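"""Exception hierarchy shared across the package."""


class CoromixError(Exception):
    """Base class for all package-specific errors."""


class InvalidProtocolError(CoromixError, ValueError):
    """A flow/infusion protocol violates a physical or design constraint."""


class GeometryError(CoromixError, ValueError):
    """Vessel/catheter geometry is degenerate or a path leaves the lumen."""


class SolverError(CoromixError, RuntimeError):
    """The transport solver could not advance under the given configuration."""


class SamplingError(CoromixError, ValueError):
    """Too few sample points or stored time steps for a statistic."""


class RangeError(CoromixError, ValueError):
    """A requested station or window lies outside the stored field extent."""


class TraceError(CoromixError, ValueError):
    """A pullback trace is degenerate or fails plausibility checks."""
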