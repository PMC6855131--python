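"""Exception types shared across the package."""


class NeurofuseError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(NeurofuseError, ValueError):
    """A user-supplied specification or config is invalid or infeasible."""


class IncompatibleGeometryError(NeurofuseError, ValueError):
    """Volume / mask grids or affines do not match."""


class IncompatibleDataError(NeurofuseError, ValueError):
    """Array shapes or subject sets do not line up."""


class UnsupportedInputError(NeurofuseError, ValueError):
    """Operation requires information the input does not carry."""


class UndefinedStatisticError(NeurofuseError, ArithmeticError):
    """A requested estimate is undefined for the given data (e.g. zero denominator)."""
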