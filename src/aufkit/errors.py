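"""Exception types shared across the package."""


class AufError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AufError, ValueError):
    """A record or argument violates the metric's domain (e.g. zero or negative usage)."""


class InvalidParameterError(AufError, ValueError):
    """A configuration parameter is outside its admissible range."""


class InsufficientSampleError(AufError, ValueError):
    """An operation needs more observations than were supplied (e.g. a sample SD at n < 2)."""


class ConfigurationError(AufError, ValueError):
    """A simulation configuration is internally inconsistent (e.g. ambiguous event overlap)."""


class ParseError(AufError, ValueError):
    """An input file could not be parsed into valid records; carries offending line numbers."""

    def __init__(self, message: str, lines: tuple[int, ...] = ()):
        super().__init__(message)
        self.lines = lines
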