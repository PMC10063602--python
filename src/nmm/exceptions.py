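"""Exception hierarchy for the nmm package."""


class NmmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NmmError):
    """A file could not be parsed (names the offending row/column)."""


class ValidationError(NmmError):
    """Inputs violate a structural contract (duplicates, bad categories, ...)."""


class UnusableDataError(NmmError):
    """The data carry no usable information (e.g. every item is extreme)."""


class LinkageError(NmmError):
    """The missing-data design is disconnected or shares no anchor items."""


class ConvergenceError(NmmError):
    """An iterative estimator failed to reach its tolerance."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
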