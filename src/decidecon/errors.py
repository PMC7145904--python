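"""Exception hierarchy shared across the package."""


class DecideconError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DecideconError, ValueError):
    """An input violates a documented precondition (bad value, unknown id, ...)."""


class EstimationError(DecideconError, RuntimeError):
    """An estimator cannot produce a result from the data it was given."""
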