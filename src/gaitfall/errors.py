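"""Exception hierarchy shared across pipeline stages."""


class GaitfallError(Exception):
    """Base class for all package errors."""


class ParameterError(GaitfallError, ValueError):
    """An argument or configuration value is out of its valid domain."""


class DataError(GaitfallError, ValueError):
    """Input data violates a structural precondition (too few strides, ...)."""


class DetectionError(GaitfallError, RuntimeError):
    """Event detection failed; message names the offending channel."""


class SchemaError(GaitfallError, KeyError):
    """A required column/feature is missing; message names it."""


class UndefinedValueError(GaitfallError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. zero mean)."""
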