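"""Exception hierarchy.

All errors derive from :class:`MnrmError` so callers can catch package
failures with a single except clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class MnrmError(Exception):
    """Base class for all package errors."""


class ShapeError(MnrmError, ValueError):
    """Array dimensions are inconsistent with each other or with metadata."""


class NumericError(MnrmError, ValueError):
    """Non-finite values where finite ones are required."""


class InvalidCategoriesError(MnrmError, ValueError):
    """Category count too small for the requested weight vector."""


class DegenerateWeightsError(MnrmError, ValueError):
    """Weight vector would be constant and cancel from the model."""


class NoMidpointError(MnrmError, ValueError):
    """Midscale weights requested for a scale without a single midpoint."""


class ZeroRangeError(MnrmError, ValueError):
    """Rating-scale bounds coincide; rescaling is undefined."""


class MappingError(MnrmError, ValueError):
    """Item-to-trait map is inconsistent with the item set."""


class WeightRangeError(MnrmError, ValueError):
    """Faking scoring weight outside the unit interval."""


class CapabilityError(MnrmError, ValueError):
    """Requested numerical method not available for this configuration."""


class NestingError(MnrmError, ValueError):
    """Model pair handed to a nested test is not properly nested."""


class ConfigurationError(MnrmError, ValueError):
    """Invalid configuration file or simulation design."""


class ConvergenceError(MnrmError, RuntimeError):
    """Estimation failed to converge; carries the convergence trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
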