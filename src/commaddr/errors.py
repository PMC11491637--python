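"""Exception types shared across the pipeline stages."""


class CommaddrError(Exception):
    """Base class for all package errors."""


class ConfigError(CommaddrError):
    """A configuration problem: missing mapped column, empty reference,
    empty keyword set, out-of-range threshold."""


class InputValidationError(CommaddrError):
    """Input data violates a contract: coordinate out of range, duplicate
    reference address with conflicting coordinates, mismatched extracts."""


class RuleSetError(CommaddrError):
    """A correction rule set failed load-time validation (pattern does not
    compile, or a replacement reintroduces its own pattern)."""
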