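"""Exception types shared across the package."""


class ForagesimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ForagesimError, ValueError):
    """A parameter, key, or species tag is invalid or out of range."""


class ComputationError(ForagesimError, ArithmeticError):
    """A state variable became non-finite during simulation."""


class AggregationError(ForagesimError, ValueError):
    """Trials passed to an aggregator are inconsistent (e.g. mismatched lengths)."""
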