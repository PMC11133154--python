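"""Synthetic calibration screenshots and browsing sessions with ground truth.

Real recordings of scrollable-page browsing require a browser, an eye
tracker and a participant; none of that is available to an automated test.
This module fabricates the same artefacts with fully known geometry: a
marker screenshot whose viewport corners are exact, a tall full-page image,
and a session table whose gaze samples are generated *from* chosen
page coordinates through the true (clamped, latency-delayed) viewport
offset timeline. Because the ground truth is recorded alongside, the whole
pipeline — calibration, correction, heatmap — can be verified end to end.

The generator mirrors the physical causal chain: a wheel event at time t
becomes visible on the display ``display_latency`` ms later (optionally
quantised to monitor frame boundaries), at which instant the offset jumps
by ``scroll_pixels`` per notch and is clamped to the page, exactly as a
browser with smooth scrolling disabled behaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import DEFAULT_MARKER_COLORS, Calibration
from .errors import ConfigurationError, GeometryError, ValidationError
from .fixed_areas import Bundle, Rule
from .session_io import (
    DATA,
    GAZE_X,
    GAZE_Y,
    TIMESTAMP,
    ScrollEvent,
    format_event,
    write_corrected,
)


@dataclass(frozen=True)
class PageSpec:
    """Geometry and dynamics of a synthetic browsing setup.

    The full-page image is ``image_width`` x ``image_height`` with
    ``image_width`` equal to the viewport width (the standard full-page
    screenshot convention). ``display_latency`` is the true delay in ms
    between a wheel input and the visible change; the matching correction
    run should use an equal ``scroll_lag``. Optional fixed-area bundles and
    rules describe sticky page chrome.
    """

    screen_width: int = 1920
    screen_height: int = 1080
    viewport_top_left: tuple[int, int] = (0, 87)
    viewport_bottom_right: tuple[int, int] = (1919, 1079)
    scroll_pixels: float = 125.0
    image_height: int = 4377
    display_latency: float = 0.0
    starting_offset: float = 0.0
    bundles: tuple[Bundle, ...] = ()
    rules: tuple[Rule, ...] = ()

    def __post_init__(self):
        # Calibration construction validates the viewport geometry.
        cal = self.calibration
        if self.image_height < cal.viewport_height:
            raise ValidationError(
                f"image_height ({self.image_height}) must be >= viewport height "
                f"({cal.viewport_height})"
            )
        if self.display_latency < 0:
            raise ValidationError("display_latency must be >= 0")
        if len(self.bundles) != len(self.rules):
            raise ConfigurationError(
                f"bundles and rules must pair positionally: "
                f"{len(self.bundles)} vs {len(self.rules)}"
            )

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            self.screen_width,
            self.screen_height,
            self.viewport_top_left,
            self.viewport_bottom_right,
            self.scroll_pixels,
        )

    @property
    def image_width(self) -> int:
        return self.calibration.viewport_width

    @property
    def max_scroll(self) -> float:
        return self.calibration.max_scroll(self.image_height)


@dataclass
class SyntheticSession:
    """A generated session plus its ground truth.

    ``truth`` has one row per coordinate-bearing session row, in the same
    order: the full-page coordinates the sample was generated from, the
    true scrolled offset at its timestamp, and whether the sample falls in
    an *ambiguity window* — strictly between an event's timestamp and its
    visibility time, where no mapping method can know the display state
    without frame-exact knowledge of the renderer.
    """

    session: pd.DataFrame
    truth: pd.DataFrame
    events: list[ScrollEvent]
    page: PageSpec = field(repr=False, default=None)


def generate_calibration_image(
    page: PageSpec,
    marker_colors: tuple[tuple[int, int, int], tuple[int, int, int]] = DEFAULT_MARKER_COLORS,
    marker_size: int = 12,
    background: tuple[int, int, int] = (225, 225, 225),
) -> Image.Image:
    """Screen-sized screenshot of a synthetic marker page.

    One square of the first colour has its top-left pixel exactly at the
    viewport's top-left corner; one square of the second colour has its
    bottom-right pixel exactly at the viewport's bottom-right corner.
    """
    cal = page.calibration
    tlx, tly = cal.viewport_top_left
    brx, bry = cal.viewport_bottom_right
    size = max(1, min(marker_size, cal.viewport_width, cal.viewport_height))
    if tlx + size - 1 >= brx - size + 1 and tly + size - 1 >= bry - size + 1:
        raise GeometryError(
            f"marker squares of size {size} would overlap inside the "
            f"{cal.viewport_width}x{cal.viewport_height} viewport"
        )
    arr = np.empty((page.screen_height, page.screen_width, 3), dtype=np.uint8)
    arr[:] = background
    arr[tly : tly + size, tlx : tlx + size] = marker_colors[0]
    arr[bry - size + 1 : bry + 1, brx - size + 1 : brx + 1] = marker_colors[1]
    return Image.fromarray(arr)


def generate_page_image(page: PageSpec, band_height: int = 200) -> Image.Image:
    """Deterministic patterned full-page image (banded vertical gradient).

    Gives the heatmap something visually structured to overlay; content is
    arbitrary but reproducible.
    """
    h, w = page.image_height, page.image_width
    y = np.arange(h)
    band = (y // band_height) % 2
    grad = (255 * y / max(1, h - 1)).astype(np.uint8)
    arr = np.zeros((h, w, 3), dtype=np.uint8)
    arr[:, :, 0] = (200 - 120 * band)[:, None]
    arr[:, :, 1] = grad[:, None]
    arr[:, :, 2] = 180
    arr[:, ::128, :] = 90  # vertical rules every 128 px
    return Image.fromarray(arr)


def _visibility_time(t: float, page: PageSpec, refresh_rate: float | None, n_frame: int) -> float:
    if refresh_rate is None:
        return t + page.display_latency
    fd = 1000.0 / refresh_rate
    return (math.floor(t / fd) + n_frame) * fd


class _State:
    __slots__ = ("scrolled", "now")


def generate_session(
    page: PageSpec,
    n_samples: int,
    sampling_rate: float = 100.0,
    scroll_script: list[tuple[float, int]] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    fixed_area_bias: float = 0.25,
    refresh_rate: float | None = None,
    n_frame: int = 1,
    start_time: float = 0.0,
) -> SyntheticSession:
    """Generate a browsing session over ``page`` with known ground truth.

    ``scroll_script`` is a list of ``(time_ms, notches)`` with positive
    notches meaning scroll *down*; ``None`` draws a random script from the
    seed. Each script entry becomes one wheel event row whose ``Data``
    string uses the key:value grammar with delta = -120 per down-notch and
    +120 per up-notch and the mouse at the viewport centre.

    Gaze targets are integer page coordinates drawn uniformly from the
    region visible at each sample's timestamp (or, with probability
    ``fixed_area_bias`` when fixed areas are active, from inside a fixed
    area); the recorded screen coordinates are derived through the true
    offset timeline, so correction with ``scroll_lag`` equal to the
    display latency inverts the generation exactly. ``noise_sd`` adds
    optional zero-mean Gaussian screen noise (default off so exactness
    tests stay exact). With ``refresh_rate`` set, visibility times are
    quantised to the ``n_frame``-th monitor frame boundary after the event
    instead of a fixed latency.

    Deterministic: equal arguments (including ``seed``) give identical
    output.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be > 0")
    if n_samples < 0:
        raise ValidationError("n_samples must be >= 0")
    rng = np.random.default_rng(seed)
    cal = page.calibration
    tlx, tly = cal.viewport_top_left
    vw, vh = cal.viewport_width, cal.viewport_height
    max_scroll = page.max_scroll
    dt = 1000.0 / sampling_rate
    span_end = start_time + n_samples * dt

    if scroll_script is None:
        n_events = int(rng.integers(0, max(1, n_samples // 8) + 1))
        times = np.sort(rng.uniform(start_time, span_end, size=n_events))
        signs = rng.choice([-1, 1], size=n_events, p=[0.3, 0.7])
        mags = rng.integers(1, 4, size=n_events)
        scroll_script = [(float(t), int(s * m)) for t, s, m in zip(times, signs, mags)]
    for t, k in scroll_script:
        if not (start_time <= t <= span_end):
            raise ConfigurationError(
                f"scroll_script time {t} outside session span [{start_time}, {span_end}]"
            )
        if k == 0:
            raise ConfigurationError("scroll_script notches must be non-zero")

    # true offset timeline: clamped fold at each event's visibility time
    mouse = ((tlx + cal.viewport_bottom_right[0]) // 2, (tly + cal.viewport_bottom_right[1]) // 2)
    start_offset = min(max(float(page.starting_offset), 0.0), max_scroll)
    events: list[ScrollEvent] = []
    visible_times: list[float] = []
    offsets_after: list[float] = []
    s = start_offset
    for t, k in scroll_script:
        events.append(ScrollEvent(delta=-120 * k, mouse_x=mouse[0], mouse_y=mouse[1], timestamp=t))
        v = _visibility_time(t, page, refresh_rate, n_frame)
        visible_times.append(v)
        s = min(max(s + k * page.scroll_pixels, 0.0), max_scroll)
        offsets_after.append(s)

    def offset_at(t: float) -> float:
        s = start_offset
        for v, after in zip(visible_times, offsets_after):
            if v <= t:
                s = after
        return s

    sample_times = start_time + np.arange(n_samples) * dt
    truth_rows = []
    sample_rows = []
    for t in sample_times:
        off = offset_at(t)
        st = _State()
        st.scrolled = off
        st.now = t
        live = [a for b, r in zip(page.bundles, page.rules) if r(st) for a in b.areas]

        screen_x = screen_y = None
        if live and rng.random() < fixed_area_bias:
            area = live[int(rng.integers(len(live)))]
            sr = area.screen_rect
            lo_x, hi_x = max(sr.left, tlx), min(sr.right, cal.viewport_bottom_right[0])
            lo_y, hi_y = max(sr.top, tly), min(sr.bottom, cal.viewport_bottom_right[1])
            if lo_x <= hi_x and lo_y <= hi_y:
                screen_x = float(rng.integers(lo_x, hi_x + 1))
                screen_y = float(rng.integers(lo_y, hi_y + 1))
        if screen_x is None:
            page_x = float(rng.integers(0, page.image_width))
            page_y = off + float(rng.integers(0, vh))
            screen_x = page_x + tlx
            screen_y = page_y - off + tly

        # ground truth replays the capture/redirect semantics inline
        hit = None
        for area in live:
            sr = area.screen_rect
            if sr.left <= screen_x <= sr.right and sr.top <= screen_y <= sr.bottom:
                hit = area
                break
        if hit is not None:
            sr, mr = hit.screen_rect, hit.image_rect
            fx = (mr.width - 1) / (sr.width - 1) if sr.width > 1 else 0.0
            fy = (mr.height - 1) / (sr.height - 1) if sr.height > 1 else 0.0
            true_x = mr.left + (screen_x - sr.left) * fx
            true_y = mr.top + (screen_y - sr.top) * fy
        else:
            true_x = screen_x - tlx
            true_y = screen_y - tly + off

        if noise_sd > 0:
            screen_x += rng.normal(0.0, noise_sd)
            screen_y += rng.normal(0.0, noise_sd)

        ambiguous = any(te < t < v for te, v in zip((e.timestamp for e in events), visible_times))
        truth_rows.append((t, true_x, true_y, off, ambiguous))
        sample_rows.append((t, screen_x, screen_y))

    # interleave event and sample rows chronologically; events first on ties
    tagged = [(e.timestamp, 0, i, e) for i, e in enumerate(events)]
    tagged += [(row[0], 1, i, row) for i, row in enumerate(sample_rows)]
    tagged.sort(key=lambda item: (item[0], item[1], item[2]))

    records = []
    for t, kind, _, payload in tagged:
        if kind == 0:
            records.append({TIMESTAMP: t, DATA: format_event(payload),
                            GAZE_X: np.nan, GAZE_Y: np.nan})
        else:
            records.append({TIMESTAMP: t, DATA: np.nan,
                            GAZE_X: payload[1], GAZE_Y: payload[2]})
    session = pd.DataFrame.from_records(
        records, columns=[TIMESTAMP, DATA, GAZE_X, GAZE_Y]
    )
    truth = pd.DataFrame(
        truth_rows, columns=[TIMESTAMP, "Page.X", "Page.Y", "Offset", "Ambiguous"]
    )
    return SyntheticSession(session=session, truth=truth, events=events, page=page)


def save_synthetic(syn: SyntheticSession, directory) -> dict[str, Path]:
    """Write session.csv, truth.csv, calibration.png and page.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "session": directory / "session.csv",
        "truth": directory / "truth.csv",
        "calibration_image": directory / "calibration.png",
        "page_image": directory / "page.png",
    }
    write_corrected(syn.session, paths["session"])
    syn.truth.to_csv(paths["truth"], index=False)
    generate_calibration_image(syn.page).save(paths["calibration_image"])
    generate_page_image(syn.page).save(paths["page_image"])
    return paths
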