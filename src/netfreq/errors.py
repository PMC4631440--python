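"""Exception hierarchy for netfreq.

All library errors derive from :class:`NetfreqError` so callers can catch a
single base class; each leaf also derives from the matching builtin so that
generic handlers (``except ValueError``) keep working.
"""


class NetfreqError(Exception):
    """Base class for all netfreq errors."""


class InvalidSampleError(NetfreqError, ValueError):
    """The input sample is empty or contains non-finite values."""


class InvalidParameterError(NetfreqError, ValueError):
    """A parameter is outside its documented domain (e.g. negative zeta)."""


class DegenerateSampleError(NetfreqError, ValueError):
    """No positive scale exists to build a zeta grid (constant sample)."""


class UndefinedIndexError(NetfreqError, ArithmeticError):
    """The homogeneity index is undefined (mode value is zero)."""


class ConfigurationError(NetfreqError, ValueError):
    """Unknown distribution family, bad parameter set, or missing column."""


class IngestionError(NetfreqError, ValueError):
    """A file yielded no parseable numeric values."""
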