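"""Exception hierarchy shared across the package."""


class NMJQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(NMJQuantError, ValueError):
    """An argument or data structure violates a documented invariant."""


class InsufficientDataError(NMJQuantError):
    """Too few observations to apply a procedure (e.g. <8 noise windows)."""


class FormatError(NMJQuantError):
    """A file does not conform to the expected text format."""


class UndefinedEstimateError(NMJQuantError):
    """The estimator is mathematically undefined for these inputs
    (e.g. failure-based quantal content with zero failures)."""
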