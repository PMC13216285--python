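"""Exception hierarchy for trenshsim."""


class TrenshError(Exception):
    """Base class for all trenshsim errors."""


class InvalidGeometryError(TrenshError, ValueError):
    """A vessel dimension (length, radius) or viscosity is non-positive."""


class ConfigurationError(TrenshError, KeyError):
    """A required configuration entry is missing or inconsistent."""


class TopologyError(TrenshError, ValueError):
    """A graph construction step references a nonexistent node or vessel."""


class SingularSystemError(TrenshError, ValueError):
    """The flow system has no unique solution (open or disconnected circuit)."""


class NumericError(TrenshError, ArithmeticError):
    """A solve produced NaN or Inf."""


class ParameterError(TrenshError, ValueError):
    """An operation was called with an out-of-range parameter."""


class ConsistencyError(TrenshError, ValueError):
    """Two inputs that must share a topology or scenario do not."""


class ParseError(TrenshError, ValueError):
    """A serialized network or config file violates the schema."""
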