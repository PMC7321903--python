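"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: usage errors -> 2, data/format
errors -> 3, model errors -> 4.
"""


class RetinotractError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(RetinotractError):
    """Caller violated a precondition (empty input, bad argument)."""

    exit_code = 2


class FormatError(RetinotractError):
    """A file does not parse under its declared standard."""

    exit_code = 3


class SizingError(UsageError):
    """A phantom grid is too small to contain the requested geometry."""


class GeometryError(RetinotractError):
    """Degenerate geometry (zero-length streamline, sheared affine...)."""

    exit_code = 3


class ModelError(RetinotractError):
    """A numerical model cannot be evaluated or fit on the given input."""

    exit_code = 4
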