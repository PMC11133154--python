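"""Session-table loading, validation and the wheel-event grammar.

A *session table* is a chronologically ordered :class:`pandas.DataFrame`
with one row per eye-tracker sample or input event:

``Timestamp``
    Milliseconds; non-decreasing over rows.
``Data``
    Free-form event string, or missing. Mouse-wheel events are encoded as
    semicolon-separated ``key:value`` pairs, e.g.
    ``"X:1478;Y:399; MouseEvent:WM_MOUSEWHEEL; ScrollDelta:-120;"``.
``Gaze.X`` / ``Gaze.Y`` and/or ``Fixation.X`` / ``Fixation.Y``
    Screen-pixel coordinates, origin at the screen's top-left corner,
    y increasing downward. At least one pair of columns must exist;
    within a row the two members of a pair are both present or both
    missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EventParseError, OrderingError, SchemaError, ValidationError

TIMESTAMP = "Timestamp"
DATA = "Data"
GAZE_X = "Gaze.X"
GAZE_Y = "Gaze.Y"
FIXATION_X = "Fixation.X"
FIXATION_Y = "Fixation.Y"

#: the two recognised coordinate pairs, in preference order
COORDINATE_PAIRS = ((GAZE_X, GAZE_Y), (FIXATION_X, FIXATION_Y))

WHEEL_EVENT = "WM_MOUSEWHEEL"


@dataclass(frozen=True)
class ScrollEvent:
    """One mouse-wheel notch event parsed from a ``Data`` string.

    ``delta`` is the raw signed ScrollDelta (conventionally a multiple of
    120; positive = wheel up, negative = wheel down). ``mouse_x`` /
    ``mouse_y`` may be ``None`` when the event string carried no cursor
    position; such events cannot be located relative to the viewport.
    ``timestamp`` is attached by the caller from the row.
    """

    delta: int
    mouse_x: int | None = None
    mouse_y: int | None = None
    timestamp: float | None = None


def _split_pairs(data: str) -> dict[str, str]:
    pairs: dict[str, str] = {}
    for chunk in data.split(";"):
        chunk = chunk.strip()
        if not chunk or ":" not in chunk:
            continue
        key, value = chunk.split(":", 1)
        pairs[key.strip()] = value.strip()
    return pairs


def parse_event(data: object, row: int | None = None) -> ScrollEvent | None:
    """Parse a ``Data`` cell into a :class:`ScrollEvent`, or ``None``.

    Only ``MouseEvent:WM_MOUSEWHEEL`` strings produce events; clicks, key
    presses, missing cells and arbitrary text all return ``None``. Keys are
    case-sensitive; whitespace around keys, values and semicolons is
    tolerated; a trailing semicolon is optional; unknown keys are ignored.

    Raises
    ------
    EventParseError
        If the string declares a wheel event but ScrollDelta is absent,
        non-integer, or zero.
    """
    if data is None or (isinstance(data, float) and math.isnan(data)):
        return None
    if not isinstance(data, str):
        return None
    if WHEEL_EVENT not in data:
        return None
    pairs = _split_pairs(data)
    if pairs.get("MouseEvent") != WHEEL_EVENT:
        return None
    where = "" if row is None else f" (row {row})"
    if "ScrollDelta" not in pairs:
        raise EventParseError(f"wheel event without ScrollDelta{where}: {data!r}", row=row)
    try:
        delta = int(pairs["ScrollDelta"])
    except ValueError:
        raise EventParseError(
            f"non-integer ScrollDelta {pairs['ScrollDelta']!r}{where}", row=row
        ) from None
    if delta == 0:
        raise EventParseError(f"ScrollDelta must be non-zero{where}", row=row)

    def _coord(key: str) -> int | None:
        if key not in pairs:
            return None
        try:
            return int(pairs[key])
        except ValueError:
            return None

    return ScrollEvent(delta=delta, mouse_x=_coord("X"), mouse_y=_coord("Y"))


def format_event(event: ScrollEvent) -> str:
    """Render a :class:`ScrollEvent` back into the key:value grammar."""
    parts = []
    if event.mouse_x is not None:
        parts.append(f"X:{event.mouse_x}")
    if event.mouse_y is not None:
        parts.append(f"Y:{event.mouse_y}")
    parts.append(f"MouseEvent:{WHEEL_EVENT}")
    parts.append(f"ScrollDelta:{event.delta}")
    return ";".join(parts) + ";"


def present_pairs(table: pd.DataFrame) -> tuple[tuple[str, str], ...]:
    """The coordinate pairs whose columns exist in ``table``."""
    return tuple(p for p in COORDINATE_PAIRS if p[0] in table.columns and p[1] in table.columns)


def validate_session(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a session table and return it with numeric coordinate dtypes.

    Checks: the mandatory columns exist (``Timestamp`` plus at least one
    complete coordinate pair), timestamps are non-decreasing, and within
    each row both members of a coordinate pair are present or both missing.
    """
    if TIMESTAMP not in table.columns:
        raise SchemaError(f"missing mandatory column {TIMESTAMP!r}")
    pairs = present_pairs(table)
    if not pairs:
        missing = [c for pair in COORDINATE_PAIRS for c in pair if c not in table.columns]
        raise SchemaError(
            "need at least one complete coordinate pair "
            f"({GAZE_X}/{GAZE_Y} or {FIXATION_X}/{FIXATION_Y}); absent columns: {missing}"
        )

    table = table.copy()
    table[TIMESTAMP] = pd.to_numeric(table[TIMESTAMP])
    ts = table[TIMESTAMP].to_numpy(dtype=float)
    if len(ts) > 1:
        bad = np.nonzero(np.diff(ts) < 0)[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise OrderingError(
                f"timestamps not chronologically ordered: row {row} "
                f"(t={ts[row]}) precedes row {row - 1} (t={ts[row - 1]})",
                row=row,
            )
    for cx, cy in pairs:
        table[cx] = pd.to_numeric(table[cx])
        table[cy] = pd.to_numeric(table[cy])
        lonely = table[cx].isna() != table[cy].isna()
        if lonely.any():
            row = int(np.nonzero(lonely.to_numpy())[0][0])
            raise ValidationError(
                f"row {row}: exactly one of {cx}/{cy} is missing; "
                "pair members must be both present or both absent"
            )
    if DATA not in table.columns:
        table[DATA] = pd.Series([np.nan] * len(table), dtype=object)
    return table


def load_session(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a session CSV.

    ``column_map`` renames vendor-specific column names onto the canonical
    ones (e.g. ``{"ET_TimeSignal": "Timestamp"}``) before validation.
    Missing values may be written as empty fields or ``NA``.
    """
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if column_map:
        table = table.rename(columns=column_map)
    return validate_session(table)


def write_corrected(table: pd.DataFrame, path) -> None:
    """Write a (corrected) session table as CSV; missing cells become ``NA``.

    Round-trips exactly: reading the file back with :func:`load_session`
    reproduces the table, including missing values.
    """
    table.to_csv(path, index=False, na_rep="NA")
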