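import numpy as np
import pandas as pd
import pytest

from scrollgaze import scroll_calibration_manual

WHEEL_55095 = "X:1478;Y:399; MouseEvent:WM_MOUSEWHEEL; ScrollDelta:-120;"


@pytest.fixture
def sample_session() -> pd.DataFrame:
    """Four-row session extract: gaze + fixation columns, one wheel event."""
    return pd.DataFrame(
        {
            "Timestamp": [55080, 55089, 55095, 55097],
            "Data": [np.nan, np.nan, WHEEL_55095, np.nan],
            "Gaze.X": [803.0, 794.0, np.nan, 805.0],
            "Gaze.Y": [384.0, 375.0, np.nan, 387.0],
            "Fixation.X": [783.0, 783.0, np.nan, 783.0],
            "Fixation.Y": [380.0, 380.0, np.nan, 380.0],
        }
    )


@pytest.fixture
def hd_calibration():
    """Full-screen 1920x1080 viewport, 125 px per wheel notch."""
    return scroll_calibration_manual(1920, 1080, (0, 0), (1919, 1079), 125)
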