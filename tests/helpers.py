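"""Shared builders for randomized correction scenarios.

Scenario generation deliberately stresses the awkward regimes: clamping at
both page ends, rapid alternating scrolls, lags differing from the true
display latency, windowing, time shifts, and overlapping fixed areas.
"""

from __future__ import annotations

import numpy as np

from scrollgaze import (
    Bundle,
    CorrectionConfig,
    FixedArea,
    PageSpec,
    Rect,
    always_active,
    generate_session,
    scrolled_at_least,
    scrolled_less_than,
)

RULE_MAKERS = (
    lambda rng, max_scroll: always_active(),
    lambda rng, max_scroll: scrolled_less_than(float(rng.integers(0, max(1, int(max_scroll)) + 1))),
    lambda rng, max_scroll: scrolled_at_least(float(rng.integers(0, max(1, int(max_scroll)) + 1))),
)


def random_rect(rng, left, top, right, bottom, max_w=40, max_h=40) -> Rect:
    """Random inclusive rectangle within the given inclusive bounds."""
    w = int(rng.integers(1, min(max_w, right - left + 1) + 1))
    h = int(rng.integers(1, min(max_h, bottom - top + 1) + 1))
    x = int(rng.integers(left, right - w + 2))
    y = int(rng.integers(top, bottom - h + 2))
    return Rect(x, y, x + w - 1, y + h - 1)


def random_fixed_areas(rng, page_kwargs) -> tuple[tuple[Bundle, ...], tuple]:
    tlx, tly = page_kwargs["viewport_top_left"]
    brx, bry = page_kwargs["viewport_bottom_right"]
    iw = brx - tlx + 1
    ih = page_kwargs["image_height"]
    vh = bry - tly + 1
    max_scroll = max(0, ih - vh)
    bundles, rules = [], []
    for _ in range(int(rng.integers(1, 3))):
        areas = []
        for _ in range(int(rng.integers(1, 3))):
            screen = random_rect(rng, tlx, tly, brx, bry)
            if rng.random() < 0.5:  # equal-size target: pure translation
                ix = int(rng.integers(0, iw - screen.width + 1))
                iy = int(rng.integers(0, ih - screen.height + 1))
                image = Rect(ix, iy, ix + screen.width - 1, iy + screen.height - 1)
            else:
                image = random_rect(rng, 0, 0, iw - 1, ih - 1)
            areas.append(FixedArea(screen, image))
        bundles.append(Bundle(tuple(areas)))
        rules.append(RULE_MAKERS[int(rng.integers(len(RULE_MAKERS)))](rng, max_scroll))
    return tuple(bundles), tuple(rules)


def random_page(rng, with_areas: bool | None = None) -> PageSpec:
    """Small random page geometry; tight pages make clamping frequent."""
    vw = int(rng.integers(60, 200))
    vh = int(rng.integers(60, 160))
    tlx = int(rng.integers(0, 40))
    tly = int(rng.integers(0, 40))
    kwargs = dict(
        screen_width=tlx + vw + int(rng.integers(0, 30)),
        screen_height=tly + vh + int(rng.integers(0, 30)),
        viewport_top_left=(tlx, tly),
        viewport_bottom_right=(tlx + vw - 1, tly + vh - 1),
        scroll_pixels=float(rng.integers(10, 70)),
        image_height=vh + int(rng.integers(0, 3 * vh)),
        display_latency=float(rng.choice([0.0, 5.0, 8.333, 16.0, 25.0])),
        starting_offset=float(rng.integers(0, 2 * vh)),
    )
    if with_areas is None:
        with_areas = rng.random() < 0.5
    if with_areas:
        kwargs["bundles"], kwargs["rules"] = random_fixed_areas(rng, kwargs)
    return PageSpec(**kwargs)


def aggressive_script(rng, span: float, max_notches: int = 25) -> list[tuple[float, int]]:
    """Random script including bursts that over-scroll past both page ends."""
    n = int(rng.integers(0, 12))
    times = np.sort(rng.uniform(0.0, span, size=n))
    script = []
    for t in times:
        k = int(rng.integers(1, max_notches + 1)) * int(rng.choice([-1, 1]))
        script.append((float(t), k))
    return script


def random_scenario(seed: int, n_samples: int = 40):
    """A full random correction scenario: session, calibration, config, areas.

    The correction ``scroll_lag`` is drawn independently of the generator's
    display latency so the oracle-equivalence check also covers mismatched
    lags, windowing and time shifts.
    """
    rng = np.random.default_rng(seed)
    page = random_page(rng)
    span = n_samples * 1000.0 / 120.0
    syn = generate_session(
        page,
        n_samples=n_samples,
        sampling_rate=120.0,
        scroll_script=aggressive_script(rng, span),
        seed=int(rng.integers(2**31)),
    )
    shift = float(rng.choice([0.0, -200.0, 350.0]))
    start, stop = -np.inf, np.inf
    if rng.random() < 0.3:
        start = shift + float(rng.uniform(0, span / 3))
        stop = shift + float(rng.uniform(2 * span / 3, span))
    config = CorrectionConfig(
        image_width=page.image_width,
        image_height=page.image_height,
        time_shift=shift,
        starting_scroll=float(rng.integers(0, int(page.max_scroll) + 1)),
        timestamp_start=start,
        timestamp_stop=stop,
        scroll_lag=float(rng.choice([0.0, 4.2, 8.333, 20.0])),
        outside_image_is_na=bool(rng.random() < 0.8),
    )
    return syn, page.calibration, config, page.bundles, page.rules
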