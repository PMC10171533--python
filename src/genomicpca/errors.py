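"""Exception hierarchy shared across the package."""


class GenomicPcaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GenomicPcaError):
    """A required column, option or parameter could not be resolved."""


class EmptyInputError(GenomicPcaError):
    """An operation produced or received zero usable records."""


class InsufficientDataError(GenomicPcaError):
    """Too few variants / subjects / indicators for the requested fit."""


class InputError(GenomicPcaError):
    """An input violates a structural precondition (shape, symmetry, frame)."""


class ConvergenceError(GenomicPcaError):
    """An iterative fit exhausted its budget without converging."""

    def __init__(self, message, last_objective=None):
        super().__init__(message)
        self.last_objective = last_objective
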