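"""Exception hierarchy for calfluor.

All package errors derive from :class:`CalfluorError` so callers can catch
one base class at pipeline boundaries.
"""


class CalfluorError(Exception):
    """Base class for all calfluor errors."""


class ParameterError(CalfluorError, ValueError):
    """A parameter is outside its documented range or malformed."""


class ShapeError(CalfluorError, ValueError):
    """Array/image shapes are inconsistent."""


class FormatError(CalfluorError, ValueError):
    """An input image or file has the wrong pixel format."""


class EmptyInputError(CalfluorError, ValueError):
    """An input contained no frames / no data."""


class PlacementError(CalfluorError, RuntimeError):
    """Synthetic cell placement failed (field too crowded)."""


class BoundaryError(CalfluorError, ValueError):
    """A patch center lies too close to the image border."""


class CardinalityError(CalfluorError, ValueError):
    """Too few items for the requested comparison."""


class NormalizationError(CalfluorError, ValueError):
    """Background trace is non-positive at some frame."""


class ConfigurationError(CalfluorError, ValueError):
    """A pipeline configuration is invalid or incomplete."""


class InsufficientDataError(CalfluorError, ValueError):
    """Too few samples for a statistical operation."""
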