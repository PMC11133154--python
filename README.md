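# scrollgaze

Deterministic mapping of eye-tracking data recorded on **scrollable pages**
(typically web pages) from screen coordinates to **full-page-image**
coordinates.

Eye trackers report gaze in screen pixels, but when a participant scrolls,
the stimulus under those pixels moves. Manual frame-by-frame coding of
screen recordings is slow, irreproducible and limited by the video frame
rate; heuristic computer-vision mapping in commercial software is opaque.
`scrollgaze` instead *replays the participant's mouse-wheel events*: each
tactile wheel notch moves the page by a fixed, calibrated number of pixels,
so the page's scrolled offset is a deterministic, clamped step function of
the event log, and every gaze or fixation sample can be mapped exactly.

For a sample at screen position (x, y) taken while the page is scrolled
`s(t)` pixels down, the full-page coordinates are

    X = x − viewport_left
    Y = y − viewport_top + s(t)

where `s(t)` accumulates `scroll_pixels` per wheel notch (down-notches add,
up-notches subtract), is clamped to `[0, image_height − viewport_height]`
after every event — a browser will not scroll past the top or bottom — and
each event takes effect `scroll_lag` milliseconds after its input message,
because a monitor can only show a change on a later refresh:

    scroll_lag = (n_frame − 1) · 1000/refresh_rate + ½ · 1000/refresh_rate

Sticky page elements (menus, sidebars, ads) that do not move with the
scroll are declared as **fixed areas**, grouped into **bundles** with
activation **rules** (e.g. "active while scrolled < 1000 px"); samples
inside an active fixed area are redirected to that element's region of the
full-page image instead of being offset.

The package also contains a synthetic-session generator with full ground
truth, so the entire pipeline — calibration, correction, heatmap — is
verifiable without any recorded data.

## Worked example

```python
import numpy as np, pandas as pd
from scrollgaze import (CorrectionConfig, eye_scroll_correct,
                        get_scroll_lag, scroll_calibration_manual)

# steady gaze at screen (400, 300), one down-notch of the wheel at t=250 ms
rows = [{"Timestamp": t, "Data": np.nan, "Gaze.X": 400.0, "Gaze.Y": 300.0}
        for t in range(0, 501, 10)]
rows.append({"Timestamp": 250,
             "Data": "X:400;Y:300;MouseEvent:WM_MOUSEWHEEL;ScrollDelta:-120;",
             "Gaze.X": np.nan, "Gaze.Y": np.nan})
session = pd.DataFrame(rows).sort_values("Timestamp", kind="stable")

cal = scroll_calibration_manual(1280, 720, (0, 0), (1279, 719), scroll_pixels=100)
cfg = CorrectionConfig(image_width=1280, image_height=5000)
out = eye_scroll_correct(session, cal, cfg)

print(out["Corrected.Gaze.Y"].dropna().iloc[0])   # 300.0
print(out["Corrected.Gaze.Y"].dropna().iloc[-1])  # 400.0
print(get_scroll_lag(60, n_frame=1))              # 8.333333333333334
```

Before the event the gaze maps to page y = 300; after the single
down-notch every subsequent sample is shifted down by exactly one notch's
worth of pixels (100), to page y = 400. The last line is the recommended
scroll lag for a 60 Hz monitor when changes appear on the very next frame:
half of one 16.67 ms frame, 8.333 ms.

The same workflow is available from the shell:

```
scrollgaze simulate  --out-dir sim --seed 11 --n-samples 500
scrollgaze calibrate --image sim/calibration.png --scroll-pixels 125 --out cal.json
scrollgaze correct   --session sim/session.csv --calibration cal.json \
                     --page-image sim/page.png --out corrected.csv
scrollgaze heatmap   --data corrected.csv --page-image sim/page.png --out heat.png
```

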