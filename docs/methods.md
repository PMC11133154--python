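# Methods

## The mapping model

A scrollable page is modelled as a tall raster (the *full-page image*) of
width equal to the viewing area's width, seen through a fixed rectangular
*viewport* on the screen. The page's state at any instant is a single
number: the *scrolled offset* `s`, the number of pixels the content has
moved up from its top. The model assumes:

- **Discrete, calibrated scrolling.** Smooth scrolling is disabled in the
  browser, so each tactile wheel notch moves the content by a fixed
  `scroll_pixels`. A raw `ScrollDelta` of magnitude `d` counts as
  `max(1, round(|d|/120))` notches (wheels conventionally report ±120 per
  notch; some drivers send multiples; sub-120 deltas are treated as one
  notch). Negative deltas scroll down (offset increases).
- **Clamping per event.** After *each* event the offset is clamped to
  `[0, image_height − viewport_height]`; over-scroll is never banked, so a
  burst of 60 down-notches at the bottom of the page followed by one
  up-notch leaves the page one notch above the bottom, as in a real
  browser.
- **Input lag.** The display shows a change only at a later monitor
  refresh. Events take effect `scroll_lag` ms after their input timestamp.
  With input arrival uniform within a frame, the expected wait until the
  n-th subsequent frame is `(n_frame − ½)·1000/refresh_rate`, which is the
  value `get_scroll_lag` recommends (8.333 ms for next-frame changes at
  60 Hz; `n_frame = 2` is a reasonable default for browser pipelines).
- **Cursor gating.** Wheel events only scroll the page when the cursor is
  inside the viewport (inclusive); events whose strings carry no cursor
  position cannot be located and are ignored with a warning.

Samples inside an *active fixed area* bypass the offset entirely: they are
redirected to that area's declared rectangle on the full-page image by an
affine per-axis map scaling the offset from the screen rectangle's corner
by `(image_extent − 1)/(screen_extent − 1)`. Equal-size rectangles reduce
to a pure translation; unequal sizes support shrink-on-scroll menus.
Overlapping active areas are resolved by declaration order (first match
wins) — the choice is arbitrary but deterministic and user-controllable.
Rules are evaluated on the *effective* (post-lag, clamped) offset, the
same value used for y-offsetting, so bundle switching can never disagree
with the coordinate correction.

## Engine semantics and tie-breaking

Rows are processed chronologically after shifting timestamps by
`time_shift` and cropping to the closed window
`[timestamp_start, timestamp_stop]`. At each row the engine first applies
all queued events whose effective time has been reached (oldest first),
then records the `Scroll` value, then enqueues the row's own event (if
any) at `effective time = timestamp + scroll_lag`. Consequently an event
never affects its own row, and with zero lag its effect appears at the
next row at or after its timestamp — deterministic even when events and
samples share timestamps. The `Scroll` column reports the post-lag
(effective) offset; rows between an event and its visibility time still
show the old offset, matching what the participant saw.

`starting_scroll` outside `[0, max_scroll]` is clamped with a warning
rather than rejected (user measurements of mid-page starts are
approximate). Coordinates are carried as floats at input precision; with
`outside_image_is_na` (default) samples outside the viewport, and
corrected points outside the image, become missing but keep their
`Scroll` and shifted timestamp.

## The reference oracle

`reference_oracle` re-derives the same contract non-incrementally: it
collects every counted event globally, then maps each row independently
by folding the clamped updates visible at that row's timestamp, with
capture/redirect arithmetic re-implemented inline. It is O(rows × events)
and exists only as an independent cross-check; tests assert exact frame
equality with the engine on randomized sessions covering mismatched lags,
windowing, time shifts, clamping bursts and overlapping fixed areas.

## The synthetic-data generator

`synthesis.generate_session` inverts the causal chain: it draws integer
page-coordinate gaze targets from the region visible at each sample time
(or from inside an active fixed area), derives the screen coordinates
through the *true* offset timeline — events become visible
`display_latency` ms after their timestamp, or on the `n_frame`-th frame
boundary in the frame-quantised mode — and emits wheel events in the
key:value grammar with the cursor at the viewport centre. Defaults mirror
a typical desktop browsing setup: a 1920×1080 screen with the viewport
below an 87 px browser toolbar, 125 px per wheel notch, a 1920×4377
full-page image, and 100 Hz sampling.

Integer-valued targets and offsets make all the float arithmetic exact,
so recovery tests can assert bit-exact equality; optional Gaussian screen
noise (`noise_sd`, default off) breaks that exactness deliberately.
Samples falling strictly between an event's timestamp and its visibility
time are flagged *ambiguous*: in that window no mapping method can know
the display state without frame-exact renderer knowledge, so exactness
claims exclude it (when the correction lag equals the generator latency
the window is empty in practice and recovery is exact everywhere).

What the generator does **not** emulate: saccade dynamics and fixation
detection (fixations should be inferred upstream of correction), analog
or smooth scrolling, scrollbar dragging and page-up/-down keys, nested
scrollable subcomponents, and real page imagery (the page raster is an
arbitrary deterministic pattern). Passing tests therefore demonstrate the
correctness of the mapping arithmetic under the discrete-scroll model,
not robustness to violations of that model.

## Calibration

Automatic calibration detects one 4-connected region of each marker
colour (pure red top-left, pure blue bottom-right by default, both
overridable) by exact RGB match — hence the requirement for lossless
screenshots — and takes the extremal pixels as viewport corners, making
marker size irrelevant. `scroll_pixels` is always supplied by the user;
it is displayed on the marker page and read by eye, not OCR'd.

## Heatmaps

Corrected points accumulate as unit masses (optionally weighted by a
per-row column) on the image grid, are smoothed with an isotropic
Gaussian (default σ = 50 px, roughly a text paragraph at page scale),
peak-normalised, and alpha-composited with a perceptually uniform
colormap at per-pixel alpha `max_alpha · density` (default 0.6). Pixels
with zero density keep their exact original values. Fixation coordinates
are preferred over gaze when both are present, since one fixation row per
sample already encodes dwell.

## Problem sizes in the test suite

Randomized-equivalence tests use 1000 sessions of ~40 rows on small page
geometries (viewports of 60–200 px) chosen to make clamping and rule
switching frequent; round-trip recovery uses 11,000 samples across ten
random pages; calibration recovery is exhaustive over a 5×5×5×5 grid of
viewport rectangles on a 200×160 screen. These sizes exercise every code
path while keeping the whole suite under a minute.
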