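"""Screen/viewport calibration and the input-lag model.

Calibration answers three questions about the recording setup: how big the
screen is, where the scrollable viewing area sits on it, and how many
pixels one wheel notch moves the page. It can be read automatically from a
lossless screenshot of a marker page (a coloured square in the top-left
and bottom-right corners of the viewing area), or supplied by hand.

The lag model approximates the delay between a wheel input message and the
visible change on the monitor. If the arrival time of an input within a
frame is uniform, the next frame is drawn on average half a frame later;
each further frame adds a whole frame duration:

    scroll_lag = (n_frame - 1) * 1000 / refresh_rate + 0.5 * 1000 / refresh_rate

with ``n_frame`` the rank of the frame on which the change is assumed to
appear and ``refresh_rate`` in Hz; the result is milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import GeometryError, MarkerDetectionError, ValidationError

#: default marker colours: pure red marks the viewport's top-left corner,
#: pure blue its bottom-right corner (exact RGB match; use lossless PNGs).
DEFAULT_MARKER_COLORS = ((255, 0, 0), (0, 0, 255))

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class Calibration:
    """Screen geometry and scroll step of a recording setup.

    The viewport rectangle is inclusive on all sides: ``viewport_top_left``
    and ``viewport_bottom_right`` are the coordinates of the top-leftmost
    and bottom-rightmost pixels of the viewing area, so its width is
    ``br.x - tl.x + 1``.
    """

    screen_width: int
    screen_height: int
    viewport_top_left: tuple[int, int]
    viewport_bottom_right: tuple[int, int]
    scroll_pixels: float

    def __post_init__(self):
        tlx, tly = self.viewport_top_left
        brx, bry = self.viewport_bottom_right
        if not (0 <= tlx < brx < self.screen_width):
            raise ValidationError(
                "viewport x-bounds invalid: need 0 <= viewport_top_left.x < "
                f"viewport_bottom_right.x < screen_width, got {tlx}, {brx}, {self.screen_width}"
            )
        if not (0 <= tly < bry < self.screen_height):
            raise ValidationError(
                "viewport y-bounds invalid: need 0 <= viewport_top_left.y < "
                f"viewport_bottom_right.y < screen_height, got {tly}, {bry}, {self.screen_height}"
            )
        if not self.scroll_pixels > 0:
            raise ValidationError(f"scroll_pixels must be > 0, got {self.scroll_pixels}")

    @property
    def viewport_width(self) -> int:
        return self.viewport_bottom_right[0] - self.viewport_top_left[0] + 1

    @property
    def viewport_height(self) -> int:
        return self.viewport_bottom_right[1] - self.viewport_top_left[1] + 1

    def contains(self, x: float, y: float) -> bool:
        """Whether a screen point lies inside the viewport (inclusive)."""
        return (
            self.viewport_top_left[0] <= x <= self.viewport_bottom_right[0]
            and self.viewport_top_left[1] <= y <= self.viewport_bottom_right[1]
        )

    def max_scroll(self, image_height: float) -> float:
        """Largest possible scrolled offset for a page of the given height."""
        return max(0.0, float(image_height) - self.viewport_height)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["viewport_top_left"] = list(self.viewport_top_left)
        d["viewport_bottom_right"] = list(self.viewport_bottom_right)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            screen_width=int(d["screen_width"]),
            screen_height=int(d["screen_height"]),
            viewport_top_left=tuple(int(v) for v in d["viewport_top_left"]),
            viewport_bottom_right=tuple(int(v) for v in d["viewport_bottom_right"]),
            scroll_pixels=float(d["scroll_pixels"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "Calibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def scroll_calibration_manual(
    screen_width: int,
    screen_height: int,
    viewport_top_left: tuple[int, int],
    viewport_bottom_right: tuple[int, int],
    scroll_pixels: float,
) -> Calibration:
    """Build a :class:`Calibration` from hand-gathered numbers."""
    tl = tuple(int(v) for v in viewport_top_left)
    br = tuple(int(v) for v in viewport_bottom_right)
    return Calibration(int(screen_width), int(screen_height), tl, br, float(scroll_pixels))


def _as_rgb_array(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError("calibration image must be an RGB(A) raster")
    return arr[:, :, :3]


def _single_region(mask: np.ndarray, which: str) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_FOUR_CONNECTED)
    if n != 1:
        raise MarkerDetectionError(
            f"{which} marker: expected exactly one connected region of its colour, found {n}"
        )
    return labels == 1


def scroll_calibration_auto(
    image,
    scroll_pixels: float,
    marker_colors: tuple[tuple[int, int, int], tuple[int, int, int]] = DEFAULT_MARKER_COLORS,
) -> Calibration:
    """Read a :class:`Calibration` from a marker-page screenshot.

    The screen size is the image size. The viewport's top-left corner is
    the top-leftmost pixel of the (single, 4-connected) region of the first
    marker colour, and its bottom-right corner the bottom-rightmost pixel
    of the region of the second colour. Marker size is irrelevant; only the
    extremal pixels matter. ``scroll_pixels`` (displayed on the marker page)
    is read by the user and passed through.
    """
    arr = _as_rgb_array(image)
    height, width = arr.shape[:2]

    tl_color, br_color = marker_colors
    tl_region = _single_region(np.all(arr == np.asarray(tl_color), axis=2), "top-left")
    br_region = _single_region(np.all(arr == np.asarray(br_color), axis=2), "bottom-right")

    ys, xs = np.nonzero(tl_region)
    tl = (int(xs.min()), int(ys.min()))
    ys, xs = np.nonzero(br_region)
    br = (int(xs.max()), int(ys.max()))
    if not (br[0] > tl[0] and br[1] > tl[1]):
        raise GeometryError(
            f"markers out of order: bottom-right corner {br} is not below-right "
            f"of top-left corner {tl}"
        )
    return Calibration(width, height, tl, br, float(scroll_pixels))


def frame_duration(refresh_rate: float) -> float:
    """Duration of one display/video frame in milliseconds (1000 / rate)."""
    if refresh_rate <= 0:
        raise ValueError(f"refresh_rate must be > 0, got {refresh_rate}")
    return 1000.0 / refresh_rate


def get_scroll_lag(refresh_rate: float, n_frame: int = 2) -> float:
    """Recommended scroll-lag (ms) for a monitor refresh rate.

    Half a frame for the expected wait until the next refresh, plus whole
    frames for any additional rendering delay. ``n_frame=1`` is the minimum
    sensible value (change drawn on the very next frame); ``n_frame=2`` is
    a reasonable default for typical browser pipelines.
    """
    if refresh_rate <= 0:
        raise ValueError(f"refresh_rate must be > 0, got {refresh_rate}")
    if int(n_frame) != n_frame or n_frame < 1:
        raise ValueError(f"n_frame must be an integer >= 1, got {n_frame}")
    return (n_frame - 1) * 1000.0 / refresh_rate + 0.5 * 1000.0 / refresh_rate
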