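"""Exception types shared across the package."""


class EcostreamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcostreamError, ValueError):
    """An input table or argument violates a documented invariant."""


class MemoryBudgetError(EcostreamError, MemoryError):
    """A dense computation would exceed the configured memory budget.

    Raised instead of attempting an allocation that is known up front to
    be too large; callers are pointed at the streaming code path, which
    has no such limit.
    """
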