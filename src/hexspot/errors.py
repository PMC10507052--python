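"""Exception hierarchy shared across the pipeline.

Every stage raises one of these instead of a bare ValueError so that the
CLI can map failures onto exit codes (input error vs internal error).
"""


class HexspotError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HexspotError, ValueError):
    """A function argument violates its preconditions."""


class ConfigurationError(HexspotError, ValueError):
    """A configuration value (method name, threshold, permutation count) is invalid."""


class FormatError(HexspotError, ValueError):
    """An on-disk file does not conform to its documented schema."""


class ZeroVarianceError(HexspotError, ValueError):
    """A correlation was requested on a constant vector; the coefficient is undefined."""
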