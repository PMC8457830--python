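"""Exception hierarchy used across the package."""


class EscapekitError(Exception):
    """Base class for package errors."""


class ParameterError(EscapekitError, ValueError):
    """An argument is outside its allowed range."""


class ScheduleError(EscapekitError, ValueError):
    """An episode schedule is inconsistent (overlaps, unreachable starts)."""


class FormatError(EscapekitError, ValueError):
    """An input table or matrix violates its format contract."""


class InsufficientDataError(EscapekitError, ValueError):
    """Too few samples to compute the requested quantity."""


class DegenerateInputError(EscapekitError, ValueError):
    """Input is degenerate (constant signal, zero-variance fit, ...)."""


class AlignmentError(EscapekitError, ValueError):
    """Time bases of two inputs do not overlap sufficiently."""


class ConfigError(EscapekitError, ValueError):
    """A pipeline configuration file is invalid."""


class DependencyError(EscapekitError, ValueError):
    """A pipeline stage was requested without its upstream products."""
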