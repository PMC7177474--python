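"""Exception hierarchy for loopshape.

Every operational failure raises a subclass of :class:`LoopshapeError` so
callers (and the CLI) can distinguish user errors from bugs.
"""


class LoopshapeError(Exception):
    """Base class for all loopshape errors."""


class FormatError(LoopshapeError):
    """A file could not be parsed (bad ATOM record, bad number, ...)."""


class TopologyError(LoopshapeError):
    """Models of an ensemble do not share an identical atom topology."""


class SchemaError(LoopshapeError):
    """A tabular input is missing required columns."""


class ResolutionError(LoopshapeError):
    """A loop specification does not resolve against a structure."""


class InputError(LoopshapeError):
    """An argument violates an operation's precondition."""
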