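"""Package-wide exception types."""


class DiffluxError(Exception):
    """Base class for all difflux errors."""


class FormatError(DiffluxError, ValueError):
    """A model file could not be parsed in the named format."""


class ModelValidationError(DiffluxError, ValueError):
    """A model violates a structural invariant."""


class InfeasibleError(DiffluxError, RuntimeError):
    """A linear program has no feasible solution."""


class UnboundedError(DiffluxError, RuntimeError):
    """A linear program objective is unbounded."""
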