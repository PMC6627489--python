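"""Exception hierarchy shared by all analysis stages.

Each public error class carries a process exit code so the command-line
layer can map failures onto distinct shell statuses.
"""


class SurfbindError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(SurfbindError):
    """An input table does not conform to the expected column schema."""

    exit_code = 2


class ConfigError(SurfbindError):
    """Contradictory or incomplete configuration."""

    exit_code = 3


class InsufficientDataError(SurfbindError):
    """Too few usable points for the requested regression."""

    exit_code = 4


class InvalidInputError(SurfbindError):
    """A value violates a physical precondition (negative absorbance, ...)."""

    exit_code = 5


class NoBreakError(SurfbindError):
    """A tensiometry curve shows no break that beats a single straight line."""

    exit_code = 6


class InvalidShapeError(SurfbindError):
    """A tensiometry curve is not descending-then-plateau shaped."""

    exit_code = 6
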