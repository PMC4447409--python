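"""Exception hierarchy shared by all pipeline stages."""


class IvimAblateError(Exception):
    """Base class for all package errors."""


class ParameterError(IvimAblateError, ValueError):
    """A model parameter violates its validity constraints."""


class GeometryError(IvimAblateError, ValueError):
    """Phantom geometry is out of bounds or self-overlapping."""


class FitError(IvimAblateError, RuntimeError):
    """A curve fit cannot be attempted (bad inputs, too few points)."""


class FormatError(IvimAblateError, ValueError):
    """An on-disk artifact does not match the expected format."""


class InsufficientSubjectsError(IvimAblateError, ValueError):
    """Too few subjects for the requested statistical analysis."""

    exit_code = 3
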