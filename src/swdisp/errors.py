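"""Exception hierarchy shared by all swdisp modules."""


class SwdispError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SwdispError, ValueError):
    """Input data or configuration violates a documented invariant."""


class FormatError(SwdispError, ValueError):
    """An on-disk container is malformed (e.g. a required dataset is missing)."""


class DomainError(SwdispError, ValueError):
    """A request falls outside the valid domain of an operation."""


class NoSignalError(SwdispError, RuntimeError):
    """A spectrum or field contains no usable signal (e.g. identically zero)."""


class OptimizationError(SwdispError, RuntimeError):
    """A nonlinear fit failed from every attempted start."""
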