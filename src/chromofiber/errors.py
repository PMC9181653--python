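"""Exception types shared across the package."""


class ChromofiberError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(ChromofiberError, ValueError):
    """An argument violates a documented precondition."""


class GeometryInfeasibleError(ChromofiberError):
    """A requested geometry cannot be realized (volume escapes its envelope,
    linker arc length incompatible with the base-pair rise, ...)."""


class EventParseError(ChromofiberError, ValueError):
    """An event TSV file contains malformed or invalid rows."""


class UndefinedResultError(ChromofiberError):
    """A statistic is undefined for the given (e.g. empty) input."""
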