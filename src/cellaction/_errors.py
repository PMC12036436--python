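"""Exception hierarchy.

Format errors signal malformed on-disk inputs; validation errors signal
inputs that parse but violate a documented contract; capability errors
signal requests that exceed a hard computational guard.
"""


class CellActionError(Exception):
    """Base class for all package errors."""


class FormatError(CellActionError):
    """Malformed or inconsistent on-disk input."""


class ValidationError(CellActionError):
    """Input violates a documented precondition or invariant."""


class LookupError_(CellActionError):
    """Unknown id (cell, token, edge) requested."""


class CapabilityError(CellActionError):
    """Request exceeds an enumeration or size guard."""
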