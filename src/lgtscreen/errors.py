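"""Exception hierarchy for the screen.

Every error a caller can act on derives from :class:`LgtScreenError`;
configuration problems name the offending field in their message.
"""


class LgtScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LgtScreenError):
    """A parameter object violates its invariants."""


class InputError(LgtScreenError):
    """Malformed sequence or track input."""


class ParseError(LgtScreenError):
    """A file could not be parsed; message carries the line number."""


class ConsistencyError(LgtScreenError):
    """Cross-references between inputs do not line up (e.g. a hit on an unknown scaffold)."""


class PlacementError(LgtScreenError):
    """The simulator could not place implants under its spacing constraint."""


class PipelineError(LgtScreenError):
    """A pipeline stage failed; message names the stage and offending file."""
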