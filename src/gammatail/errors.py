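"""Exception hierarchy shared across the package."""


class GammatailError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GammatailError, ValueError):
    """An argument violates a documented precondition."""


class InvalidConfigError(GammatailError, ValueError):
    """A configuration file or parameter set is malformed or inconsistent."""


class DegenerateReferenceError(GammatailError, ZeroDivisionError):
    """A relative quantity was requested against a zero-valued reference."""


class ScorerContractError(GammatailError):
    """A user-supplied scorer returned different values for the same input."""


class NoValidControlError(GammatailError):
    """No control residue exists for a position (e.g. singleton class)."""


class UndefinedCorrelationError(GammatailError, ValueError):
    """Correlation requested on a constant (zero-variance) vector."""
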