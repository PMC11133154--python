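"""The correction engine: screen coordinates -> full-page-image coordinates.

The engine walks the session chronologically while maintaining the clamped,
lag-delayed scrolled offset — the number of pixels the page content has
moved up from its top. Wheel events whose cursor lies inside the viewport
change the offset by ``scroll_pixels`` per notch, ``scroll_lag``
milliseconds after their timestamp (monitors never show a change the
instant the input message arrives). The offset is clamped to
``[0, image_height - viewport_height]`` after every single event, exactly
as a browser refuses to scroll past the top or bottom of the page.

Each gaze/fixation sample is then mapped: points inside an active fixed
area are redirected to that area's full-page rectangle; all other points
are translated to viewport-origin coordinates and offset downward by the
current scrolled value.

``reference_oracle`` is a deliberately naive second implementation of the
same contract (global event replay + per-row lookup instead of an
incremental queue) kept solely so tests can cross-check the engine.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import session_io
from .calibration import Calibration
from .errors import ConfigurationError, ValidationError
from .fixed_areas import Bundle, Rule, active_areas, capture, redirect
from .session_io import parse_event, present_pairs, validate_session, write_corrected

SCROLL = "Scroll"
TIMESTAMP_SHIFTED = "Timestamp.Shifted"

_CORRECTED = {
    (session_io.GAZE_X, session_io.GAZE_Y): ("Corrected.Gaze.X", "Corrected.Gaze.Y"),
    (session_io.FIXATION_X, session_io.FIXATION_Y): (
        "Corrected.Fixation.X",
        "Corrected.Fixation.Y",
    ),
}


@dataclass
class CorrectionConfig:
    """Arguments of the correction run.

    ``time_shift`` synchronises the timestamp column to an external clock;
    rows whose shifted timestamp falls outside the closed interval
    ``[timestamp_start, timestamp_stop]`` are removed. ``starting_scroll``
    seeds the offset when the recording begins mid-page. ``scroll_lag``
    (ms) delays every event's effect; see ``calibration.get_scroll_lag``.
    With ``outside_image_is_na`` (default), samples outside the viewport —
    and corrected points outside the page image — become missing.
    """

    image_width: int
    image_height: int
    time_shift: float = 0.0
    starting_scroll: float = 0.0
    timestamp_start: float = -math.inf
    timestamp_stop: float = math.inf
    scroll_lag: float = 0.0
    outside_image_is_na: bool = True
    output_file: str = ""

    def __post_init__(self):
        if self.timestamp_start > self.timestamp_stop:
            raise ValidationError(
                f"timestamp_start ({self.timestamp_start}) must be <= "
                f"timestamp_stop ({self.timestamp_stop})"
            )
        if self.scroll_lag < 0:
            raise ValidationError(f"scroll_lag must be >= 0, got {self.scroll_lag}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError("image_width and image_height must be positive")


@dataclass
class ScrollState:
    """Scroll state visible to rules: the effective clamped offset and time."""

    scrolled: float
    now: float = 0.0
    pending: deque = field(default_factory=deque)


def notches(delta: int) -> int:
    """Signed notch count of a raw ScrollDelta.

    Wheels conventionally report ±120 per tactile notch; drivers may send
    multiples. Magnitudes below 120 still count as one notch:
    ``sign(delta) * max(1, round(|delta| / 120))``. Positive = up.
    """
    mag = max(1, round(abs(delta) / 120))
    return mag if delta > 0 else -mag


def _check_compatible(calibration: Calibration, config: CorrectionConfig) -> None:
    if config.image_width != calibration.viewport_width:
        raise ConfigurationError(
            f"full-page image width ({config.image_width}) must equal the "
            f"calibration viewport width ({calibration.viewport_width})"
        )


def _clamped_start(config: CorrectionConfig, max_scroll: float) -> float:
    start = float(config.starting_scroll)
    if not 0.0 <= start <= max_scroll:
        clamped = min(max(start, 0.0), max_scroll)
        warnings.warn(
            f"starting_scroll {start} outside [0, {max_scroll}]; clamped to {clamped}",
            stacklevel=3,
        )
        return clamped
    return start


def _window(session: pd.DataFrame, config: CorrectionConfig) -> tuple[pd.DataFrame, np.ndarray]:
    shifted = session[session_io.TIMESTAMP].to_numpy(dtype=float) + config.time_shift
    keep = (shifted >= config.timestamp_start) & (shifted <= config.timestamp_stop)
    return session.loc[keep].reset_index(drop=True), shifted[keep]


def eye_scroll_correct(
    session: pd.DataFrame,
    calibration: Calibration,
    config: CorrectionConfig,
    bundles: tuple[Bundle, ...] | list[Bundle] = (),
    rules: tuple[Rule, ...] | list[Rule] = (),
) -> pd.DataFrame:
    """Map a session's screen coordinates onto the full-page image.

    Returns the windowed session with six added columns: ``Scroll`` (the
    effective offset at each row), ``Timestamp.Shifted``, and corrected
    X/Y columns for whichever of the gaze / fixation pairs are present.
    Rows whose coordinates are missing still carry Scroll and shifted
    timestamps. If ``config.output_file`` is non-empty the result is also
    written there as CSV.
    """
    session = validate_session(session)
    _check_compatible(calibration, config)
    if len(bundles) != len(rules):
        raise ConfigurationError(
            f"bundles and rules must pair positionally: {len(bundles)} vs {len(rules)}"
        )

    out, shifted = _window(session, config)
    n = len(out)
    max_scroll = calibration.max_scroll(config.image_height)
    scroll_px = calibration.scroll_pixels
    tlx, tly = calibration.viewport_top_left
    width, height = config.image_width, config.image_height

    pairs = present_pairs(out)
    coords = {p: (out[p[0]].to_numpy(dtype=float), out[p[1]].to_numpy(dtype=float)) for p in pairs}
    corrected = {p: (np.full(n, np.nan), np.full(n, np.nan)) for p in pairs}
    data_col = out[session_io.DATA].tolist() if session_io.DATA in out.columns else [None] * n
    scroll_col = np.empty(n)

    state = ScrollState(scrolled=_clamped_start(config, max_scroll))
    pending = state.pending  # (effective_time, signed notches), FIFO == time order

    for i in range(n):
        t = shifted[i]
        state.now = t
        # apply every event whose lagged effect has become visible by now
        while pending and pending[0][0] <= t:
            _, k = pending.popleft()
            state.scrolled = min(max(state.scrolled - k * scroll_px, 0.0), max_scroll)
        scroll_col[i] = state.scrolled

        event = parse_event(data_col[i], row=i)
        if event is not None:
            if event.mouse_x is None or event.mouse_y is None:
                warnings.warn(
                    f"row {i}: wheel event without mouse coordinates; "
                    "treated as outside the viewport and ignored",
                    stacklevel=2,
                )
            elif calibration.contains(event.mouse_x, event.mouse_y):
                pending.append((t + config.scroll_lag, notches(event.delta)))

        areas = active_areas(bundles, rules, state) if bundles else ()
        for pair in pairs:
            x = coords[pair][0][i]
            y = coords[pair][1][i]
            if math.isnan(x):
                continue
            area = capture(areas, x, y) if areas else None
            if area is not None:
                cx, cy = redirect(area, x, y)
            else:
                cx = x - tlx
                cy = y - tly + state.scrolled
            if config.outside_image_is_na:
                if not calibration.contains(x, y):
                    cx = cy = np.nan
                elif not (0.0 <= cx <= width - 1 and 0.0 <= cy <= height - 1):
                    cx = cy = np.nan
            corrected[pair][0][i] = cx
            corrected[pair][1][i] = cy

    out[SCROLL] = scroll_col
    out[TIMESTAMP_SHIFTED] = shifted
    for pair in pairs:
        cxname, cyname = _CORRECTED[pair]
        out[cxname] = corrected[pair][0]
        out[cyname] = corrected[pair][1]

    if config.output_file:
        write_corrected(out, config.output_file)
    return out


def reference_oracle(
    session: pd.DataFrame,
    calibration: Calibration,
    config: CorrectionConfig,
    bundles: tuple[Bundle, ...] | list[Bundle] = (),
    rules: tuple[Rule, ...] | list[Rule] = (),
) -> pd.DataFrame:
    """Brute-force re-implementation of :func:`eye_scroll_correct`.

    Builds the complete scrolled-offset step function by replaying every
    viewport wheel event globally, then maps each row independently by
    folding the clamped updates visible at its shifted timestamp. O(rows x
    events); exists purely as an independent cross-check for tests.
    """
    session = validate_session(session)
    _check_compatible(calibration, config)
    if len(bundles) != len(rules):
        raise ConfigurationError(
            f"bundles and rules must pair positionally: {len(bundles)} vs {len(rules)}"
        )

    out, shifted = _window(session, config)
    n = len(out)
    max_scroll = calibration.max_scroll(config.image_height)
    scroll_px = calibration.scroll_pixels
    tlx, tly = calibration.viewport_top_left
    brx, bry = calibration.viewport_bottom_right
    width, height = config.image_width, config.image_height

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_scroll = _clamped_start(config, max_scroll)

    # (source row, visibility time, signed notches) for every counted event
    data_col = out[session_io.DATA].tolist() if session_io.DATA in out.columns else [None] * n
    events = []
    for i in range(n):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = parse_event(data_col[i], row=i)
        if ev is None or ev.mouse_x is None or ev.mouse_y is None:
            continue
        if tlx <= ev.mouse_x <= brx and tly <= ev.mouse_y <= bry:
            events.append((i, shifted[i] + config.scroll_lag, notches(ev.delta)))

    def offset_at(row: int) -> float:
        """Clamped fold of all events from earlier rows visible by this row."""
        t = shifted[row]
        s = start_scroll
        for src, visible, k in events:
            if src < row and visible <= t:
                s = min(max(s - k * scroll_px, 0.0), max_scroll)
        return s

    pairs = present_pairs(out)
    coords = {p: (out[p[0]].to_numpy(dtype=float), out[p[1]].to_numpy(dtype=float)) for p in pairs}
    corrected = {p: (np.full(n, np.nan), np.full(n, np.nan)) for p in pairs}
    scroll_col = np.empty(n)

    class _State:
        __slots__ = ("scrolled", "now")

    for i in range(n):
        s = offset_at(i)
        scroll_col[i] = s
        st = _State()
        st.scrolled = s
        st.now = shifted[i]
        live = [a for b, r in zip(bundles, rules) if r(st) for a in b.areas]
        for pair in pairs:
            x = coords[pair][0][i]
            y = coords[pair][1][i]
            if math.isnan(x):
                continue
            hit = None
            for area in live:
                sr = area.screen_rect
                if sr.left <= x <= sr.right and sr.top <= y <= sr.bottom:
                    hit = area
                    break
            if hit is not None:
                sr, mr = hit.screen_rect, hit.image_rect
                fx = (mr.width - 1) / (sr.width - 1) if sr.width > 1 else 0.0
                fy = (mr.height - 1) / (sr.height - 1) if sr.height > 1 else 0.0
                cx = mr.left + (x - sr.left) * fx
                cy = mr.top + (y - sr.top) * fy
            else:
                cx = x - tlx
                cy = y - tly + s
            if config.outside_image_is_na:
                inside_vp = tlx <= x <= brx and tly <= y <= bry
                if not inside_vp or not (0.0 <= cx <= width - 1 and 0.0 <= cy <= height - 1):
                    cx = cy = np.nan
            corrected[pair][0][i] = cx
            corrected[pair][1][i] = cy

    out[SCROLL] = scroll_col
    out[TIMESTAMP_SHIFTED] = shifted
    for pair in pairs:
        cxname, cyname = _CORRECTED[pair]
        out[cxname] = corrected[pair][0]
        out[cyname] = corrected[pair][1]
    return out
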