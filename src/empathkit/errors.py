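"""Exception hierarchy shared across the pipeline stages."""


class EmpathkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmpathkitError):
    """A simulation or run configuration is invalid for the requested operation."""


class ValidationError(EmpathkitError):
    """Input data violate a documented precondition (range, shape, labels)."""


class InsufficientDataError(EmpathkitError):
    """Not enough trials/intervals/samples to compute the requested quantity."""


class GenerationError(EmpathkitError):
    """A generator produced physiologically impossible output (invariant breach)."""


class QualityError(EmpathkitError):
    """Signal quality too poor to trust the result (e.g. too many corrected beats)."""
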