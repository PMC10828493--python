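"""Exception hierarchy.

All package errors derive from :class:`ChaoswidowError`, which itself derives
from :class:`ValueError` so that callers who do not care about the fine
distinctions can catch a single builtin type.
"""


class ChaoswidowError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(ChaoswidowError):
    """An argument fell outside its mathematical domain (e.g. tent-map seed)."""


class ConfigurationError(ChaoswidowError):
    """A configuration value violates its invariant (bounds, kernel sizes...)."""


class DimensionError(ChaoswidowError):
    """Two images that must share a shape do not."""


class DegenerateInputError(ChaoswidowError):
    """Input is structurally valid but degenerate for the requested operation."""


class ContractViolationError(ChaoswidowError):
    """A caller broke an operation's precondition (e.g. out-of-bounds position)."""
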