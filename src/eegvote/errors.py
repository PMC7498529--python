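"""Exception hierarchy.

``ConfigError`` covers bad parameters and infeasible requests (CLI exit 1);
``DataError`` covers unreadable, malformed or degenerate inputs (CLI exit 2).
"""


class EegvoteError(Exception):
    """Base class for all package errors."""


class ConfigError(EegvoteError):
    """Invalid or inconsistent configuration / parameters."""


class FilterDesignError(ConfigError):
    """A filter specification that cannot be realized."""


class DataError(EegvoteError):
    """Unreadable, malformed or unsupported input data."""


class DegenerateInputError(DataError):
    """Structurally valid input on which the quantity is undefined
    (e.g. the fractal dimension of a constant signal)."""
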