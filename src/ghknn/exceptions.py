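"""Exception hierarchy shared across the package."""


class GhknnError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(GhknnError, ValueError):
    """An operation was called with arguments violating its contract."""


class ConfigurationError(GhknnError, ValueError):
    """Invalid configuration values (parameters, group tables, CLI config)."""


class InvalidSequenceError(GhknnError, ValueError):
    """A sequence is empty or unusable after cleaning."""


class EmptyInputError(GhknnError, ValueError):
    """An input source yielded zero usable records."""


class NumericalError(GhknnError, ArithmeticError):
    """A numerical routine failed to meet its accuracy guarantee."""
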