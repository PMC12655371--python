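"""Exception hierarchy shared across the pipeline."""


class EffluxLimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EffluxLimError, ValueError):
    """A caller-supplied value violates a precondition (non-finite, out of range)."""


class UnresolvableP0Error(EffluxLimError):
    """No usable intrinsic-permeability source exists for a compound."""


class InsufficientDataError(EffluxLimError):
    """Too few usable data points for the requested fit."""


class InfeasibleObservationError(EffluxLimError):
    """An observation lies outside the range the model can reproduce."""


class ConvergenceError(EffluxLimError):
    """A root solve or optimisation failed to converge; diagnostics in the message."""
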