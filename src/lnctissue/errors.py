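"""Exception hierarchy used across the package.

Three error classes mirror the three failure modes of the pipeline:
malformed input text (:class:`ParseError`), inputs that parse but violate a
data-model invariant (:class:`ValidationError`), and API misuse such as
calling an operation on data in the wrong state (:class:`UsageError`).
"""


class LncTissueError(Exception):
    """Base class for all errors raised by lnctissue."""


class ParseError(LncTissueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(LncTissueError):
    """Parsed data violates an invariant (negative FPKM, start > end, ...)."""


class UsageError(LncTissueError):
    """An operation was called with arguments or state it is not defined for."""
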