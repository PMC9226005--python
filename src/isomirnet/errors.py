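"""Exception hierarchy.

All package errors derive from :class:`IsomirnetError` so callers can catch
one base class at CLI boundaries.
"""


class IsomirnetError(Exception):
    """Base class for all package errors."""


class ParameterError(IsomirnetError, ValueError):
    """A configuration value or function argument is out of its valid range."""


class PlacementError(IsomirnetError):
    """A target site cannot be planted at the requested transcript position."""


class ParseError(IsomirnetError):
    """A structured input file is malformed; message names the line."""


class DataError(IsomirnetError):
    """Inconsistent data passed between pipeline stages."""


class EncodingError(IsomirnetError):
    """A sequence contains a character outside the {A,C,G,T,U,N} alphabet."""


class UnclassifiableError(IsomirnetError):
    """No anchored offset explains an isomiR against its reference miRNA."""


class ConfigurationError(IsomirnetError):
    """A requested backend or configuration key is unavailable or unknown."""


class ModelIOError(IsomirnetError):
    """A model artifact is missing, corrupt, or of an incompatible version."""


class UndefinedMetricError(IsomirnetError, ValueError):
    """A metric is undefined for the given labels (e.g. one class only)."""
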