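"""Exception hierarchy shared by all maglink modules."""


class MaglinkError(Exception):
    """Base class for all maglink errors."""


class InvalidParameterError(MaglinkError, ValueError):
    """A precondition on an operation's parameters was violated."""


class DegenerateInputError(MaglinkError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. an all-zero count vector)."""


class ParseError(MaglinkError, ValueError):
    """A file could not be parsed; the message names the offending
    line or column where that is known."""


class ConfigError(MaglinkError, ValueError):
    """A pipeline configuration failed validation; the message names
    the offending key."""
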