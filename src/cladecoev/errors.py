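"""Exception hierarchy shared across the package."""


class CladecoevError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CladecoevError, ValueError):
    """A file does not conform to the declared dialect."""


class ValidationError(CladecoevError, ValueError):
    """An in-memory object violates one of its invariants."""


class ContractError(CladecoevError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class UndefinedIndexError(CladecoevError, ZeroDivisionError):
    """A homoplasy index is undefined (no variable characters)."""
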