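"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: usage errors exit 2 (click's default),
:class:`ContractError` and :class:`ParseError` exit 3, anything else exits 4.
"""


class SrnalinkError(Exception):
    """Base class for all toolkit errors."""


class ContractError(SrnalinkError, ValueError):
    """An input violated a documented precondition or invariant."""


class ParseError(SrnalinkError, ValueError):
    """A file could not be parsed; the message names the offending location."""
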