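"""Exception hierarchy shared across the package."""


class SymmineError(Exception):
    """Base class for all package-specific errors."""


class EncodingError(SymmineError):
    """A cell token could not be mapped to {0, 1} by the dialect."""


class ValidationError(SymmineError):
    """A cohort violates its invariants (missing cell, non-binary value)."""


class ConfigurationError(SymmineError):
    """A run was configured inconsistently (e.g. outcome column absent)."""


class DegenerateInputError(SymmineError):
    """Input is structurally valid but statistically degenerate
    (single-class outcome, constant scores, zero margin, zero pooled SD)."""


class MiningError(SymmineError):
    """Apriori / rule-generation failure (empty transactions, absent target,
    or a brute-force universe too large to enumerate)."""
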