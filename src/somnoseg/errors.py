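"""Exception hierarchy.

Contract violations (caller passed inconsistent inputs) are kept distinct
from I/O and format problems so the CLI can map them to exit codes.
"""


class SomnosegError(Exception):
    """Base class for all package errors."""


class ContractError(SomnosegError, ValueError):
    """A precondition on an operation's inputs was violated."""


class FormatError(SomnosegError, ValueError):
    """A file was readable but its contents violate the expected format."""


class ValidationError(SomnosegError, ValueError):
    """Domain data failed validation (e.g. an unknown sleep stage label)."""
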