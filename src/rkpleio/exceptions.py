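"""Exception types shared across the package."""


class InputDataError(ValueError):
    """Raised when input data violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its allowed range."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input.

    Example: a Spearman correlation where one input vector is constant.
    """


class NoInteriorMinimumError(RuntimeError):
    """Raised when the cost curve has no interior minimum on (0, r_max)."""


class MultimodalCostError(RuntimeError):
    """Raised when the cost curve shows more than one interior minimum."""
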