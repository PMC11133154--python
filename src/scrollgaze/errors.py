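"""Exception hierarchy for scrollgaze.

Every error raised by the package derives from :class:`ScrollGazeError`,
so callers (and the CLI) can catch package failures with one clause.
"""


class ScrollGazeError(Exception):
    """Base class for all scrollgaze errors."""


class SchemaError(ScrollGazeError):
    """A required column (or coordinate-pair of columns) is missing."""


class OrderingError(ScrollGazeError):
    """Timestamps are not chronologically ordered.

    ``row`` is the 0-based index of the first row whose timestamp is
    smaller than its predecessor's.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EventParseError(ScrollGazeError):
    """A wheel-event string is malformed (e.g. missing ScrollDelta)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(ScrollGazeError):
    """A record field violates its invariant; the message names the field."""


class MarkerDetectionError(ScrollGazeError):
    """A calibration marker was not found exactly once in the screenshot."""


class GeometryError(ScrollGazeError):
    """Rectangles or marker placements are geometrically inconsistent."""


class ConfigurationError(ScrollGazeError):
    """Bundle/rule or correction configuration is inconsistent."""


class ContractError(ScrollGazeError):
    """An operation was called outside its stated precondition."""
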