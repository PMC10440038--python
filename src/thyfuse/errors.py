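"""Exception hierarchy for contract, configuration and numeric failures."""


class ThyfuseError(Exception):
    """Base class for all package errors."""


class ContractError(ThyfuseError, ValueError):
    """A call violated an operation's input contract (shape, arity, range)."""


class ConfigError(ThyfuseError, ValueError):
    """A configuration failed build-time validation."""


class NumericError(ThyfuseError, FloatingPointError):
    """Non-finite values were detected in a computation."""


class SpecValidationError(ThyfuseError, ValueError):
    """A synthetic case specification is geometrically or physically invalid."""


class EmptyRegistryError(ThyfuseError, ValueError):
    """A dataset registry with zero cases was requested."""


class DegenerateSplitError(ThyfuseError, ValueError):
    """A class has too few cases to occupy all three partitions."""
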