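"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SmfishError`, so callers (notably the batch runner) can catch
pipeline failures without swallowing programming errors.
"""


class SmfishError(Exception):
    """Base class for all errors raised by smfish3d."""


class FormatError(SmfishError):
    """A file or table does not conform to the expected format."""


class BoundsError(SmfishError):
    """A region of interest falls outside the bounds of its stack."""


class DegenerateInputError(SmfishError):
    """An input is degenerate for the requested operation (e.g. constant stack)."""


class FrameError(SmfishError):
    """Two spot sets do not share a coordinate frame."""


class UndefinedRatioError(SmfishError):
    """A ratio with a zero or missing denominator was requested."""


class PlacementError(SmfishError):
    """Synthetic spot/nucleus placement failed under the separation constraint."""
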