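"""Exception hierarchy shared by all pipeline stages.

Input-shaped problems (bad tables, unknown labels, contract violations)
raise :class:`ValidationError` or one of its file-oriented siblings; failures
inside a computation (degenerate null models, rank-deficient designs) raise
:class:`ComputationError`.  The CLI maps the former to exit code 2 and the
latter to exit code 3.
"""


class ConnectomeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ConnectomeError):
    """A file has the wrong overall shape (column count, non-square matrix)."""


class ParseError(ConnectomeError):
    """A cell could not be parsed; the message names the row and column."""


class ValidationError(ConnectomeError):
    """A structurally well-formed input violates a domain invariant."""


class ComputationError(ConnectomeError):
    """A computation cannot proceed (degenerate input reached a later stage)."""
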