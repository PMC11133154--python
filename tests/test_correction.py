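import math
import warnings

import numpy as np
import pandas as pd
import pytest
from helpers import random_scenario

from scrollgaze import (
    Bundle,
    ConfigurationError,
    CorrectionConfig,
    FixedArea,
    Rect,
    always_active,
    eye_scroll_correct,
    load_session,
    reference_oracle,
    scroll_calibration_manual,
)


def wheel(x, y, delta):
    return f"X:{x};Y:{y};MouseEvent:WM_MOUSEWHEEL;ScrollDelta:{delta};"


def gaze_session(rows):
    """rows: iterable of (timestamp, data, gaze_x, gaze_y)."""
    return pd.DataFrame(rows, columns=["Timestamp", "Data", "Gaze.X", "Gaze.Y"])


@pytest.fixture
def tall_config():
    return CorrectionConfig(image_width=1920, image_height=5000)


class TestWorkedExamples:
    def test_extract_rows_before_and_after_the_wheel_event(
        self, sample_session, hd_calibration, tall_config
    ):
        """One -120 notch at 125 px/notch shifts later y-coordinates by 125."""
        out = eye_scroll_correct(sample_session, hd_calibration, tall_config)
        assert out.loc[1, "Corrected.Gaze.Y"] == 375
        assert out.loc[3, "Corrected.Gaze.Y"] == 387 + 125
        assert out.loc[0, "Corrected.Fixation.Y"] == 380
        assert out.loc[3, "Corrected.Fixation.Y"] == 380 + 125
        # x only receives the (zero) viewport translation
        assert out.loc[3, "Corrected.Gaze.X"] == 805
        assert list(out["Scroll"]) == [0, 0, 0, 125]

    def test_identity_configuration(self, hd_calibration, tall_config):
        rows = [(t, np.nan, 100.0 + t, 200.0) for t in range(0, 100, 10)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, tall_config)
        assert (out["Corrected.Gaze.X"] == out["Gaze.X"]).all()
        assert (out["Corrected.Gaze.Y"] == out["Gaze.Y"]).all()
        assert (out["Scroll"] == 0).all()

    def test_clamping_at_bottom_and_top(self):
        """Over-scrolling saturates at image_height - viewport_height, then at 0."""
        cal = scroll_calibration_manual(1000, 1000, (0, 0), (999, 999), 100)
        config = CorrectionConfig(image_width=1000, image_height=2000)
        rows = [(0, np.nan, 10.0, 10.0)]
        rows += [(10 + i, wheel(500, 500, -120), np.nan, np.nan) for i in range(20)]
        rows += [(100, np.nan, 10.0, 10.0)]
        rows += [(110 + i, wheel(500, 500, 120), np.nan, np.nan) for i in range(20)]
        rows += [(200, np.nan, 10.0, 10.0)]
        out = eye_scroll_correct(gaze_session(rows), cal, config)
        assert out.loc[21, "Scroll"] == 1000  # 20 notches x 100 px clamped at 1000
        assert out.loc[21, "Corrected.Gaze.Y"] == 1010
        assert out.loc[42, "Scroll"] == 0
        assert out.loc[42, "Corrected.Gaze.Y"] == 10

    def test_fixed_area_sample_is_scroll_independent(self):
        """A sticky-menu gaze maps to the same page point at any offset."""
        cal = scroll_calibration_manual(1000, 1000, (0, 0), (999, 999), 100)
        config = CorrectionConfig(image_width=1000, image_height=5000)
        menu = Bundle((FixedArea(Rect(0, 0, 999, 49), Rect(0, 3377, 999, 3426)),))
        rows = [(0, np.nan, 100.0, 30.0),
                (10, wheel(500, 500, -360), np.nan, np.nan),
                (20, np.nan, 100.0, 30.0)]
        out = eye_scroll_correct(gaze_session(rows), cal, config, [menu], [always_active()])
        assert out.loc[0, "Scroll"] == 0 and out.loc[2, "Scroll"] == 300
        assert out.loc[0, "Corrected.Gaze.Y"] == 30 + 3377
        assert out.loc[2, "Corrected.Gaze.Y"] == 30 + 3377
        assert out.loc[2, "Corrected.Gaze.X"] == 100


class TestEventHandling:
    def test_scroll_lag_delays_the_offset(self, hd_calibration, tall_config):
        tall_config.scroll_lag = 10.0
        rows = [(0, wheel(500, 500, -120), np.nan, np.nan),
                (5, np.nan, 10.0, 10.0),
                (9.9, np.nan, 10.0, 10.0),
                (10, np.nan, 10.0, 10.0)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, tall_config)
        assert list(out["Scroll"]) == [0, 0, 0, 125]

    def test_event_with_cursor_outside_viewport_is_ignored(self, tall_config):
        cal = scroll_calibration_manual(1920, 1080, (0, 87), (1919, 1079), 125)
        rows = [(0, wheel(500, 20, -120), np.nan, np.nan),  # over the browser tabs
                (10, np.nan, 500.0, 500.0)]
        out = eye_scroll_correct(gaze_session(rows), cal, tall_config)
        assert out.loc[1, "Scroll"] == 0

    def test_event_without_cursor_position_warns_and_is_ignored(
        self, hd_calibration, tall_config
    ):
        rows = [(0, "MouseEvent:WM_MOUSEWHEEL;ScrollDelta:-120;", np.nan, np.nan),
                (10, np.nan, 500.0, 500.0)]
        with pytest.warns(UserWarning, match="without mouse coordinates"):
            out = eye_scroll_correct(gaze_session(rows), hd_calibration, tall_config)
        assert out.loc[1, "Scroll"] == 0

    def test_multi_notch_delta_counts_proportionally(self, hd_calibration, tall_config):
        rows = [(0, wheel(500, 500, -240), np.nan, np.nan),
                (10, np.nan, 500.0, 500.0)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, tall_config)
        assert out.loc[1, "Scroll"] == 250

    def test_small_delta_counts_as_one_notch(self, hd_calibration, tall_config):
        rows = [(0, wheel(500, 500, -40), np.nan, np.nan),
                (10, np.nan, 500.0, 500.0)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, tall_config)
        assert out.loc[1, "Scroll"] == 125


class TestConfigSemantics:
    def test_window_is_a_closed_interval(self, hd_calibration):
        config = CorrectionConfig(image_width=1920, image_height=5000,
                                  timestamp_start=10, timestamp_stop=30)
        rows = [(t, np.nan, 1.0, 1.0) for t in (0, 10, 20, 30, 40)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, config)
        assert list(out["Timestamp"]) == [10, 20, 30]

    def test_time_shift_applies_before_windowing(self, hd_calibration):
        config = CorrectionConfig(image_width=1920, image_height=5000,
                                  time_shift=-100, timestamp_start=0)
        rows = [(t, np.nan, 1.0, 1.0) for t in (50, 100, 150)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, config)
        assert list(out["Timestamp"]) == [100, 150]
        assert list(out["Timestamp.Shifted"]) == [0, 50]

    def test_starting_scroll_offsets_and_clamps_with_warning(self, hd_calibration):
        config = CorrectionConfig(image_width=1920, image_height=2000,
                                  starting_scroll=99999)
        rows = [(0, np.nan, 10.0, 10.0)]
        with pytest.warns(UserWarning, match="starting_scroll"):
            out = eye_scroll_correct(gaze_session(rows), hd_calibration, config)
        assert out.loc[0, "Scroll"] == 2000 - 1080
        assert out.loc[0, "Corrected.Gaze.Y"] == 10 + 920

    def test_outside_viewport_becomes_missing(self, tall_config):
        cal = scroll_calibration_manual(1920, 1080, (0, 87), (1919, 1079), 125)
        rows = [(0, np.nan, 500.0, 20.0),  # above the viewport
                (10, np.nan, 500.0, 500.0)]
        out = eye_scroll_correct(gaze_session(rows), cal, tall_config)
        assert math.isnan(out.loc[0, "Corrected.Gaze.Y"])
        assert out.loc[1, "Corrected.Gaze.Y"] == 500 - 87

    def test_keep_outside_when_flag_disabled(self, tall_config):
        cal = scroll_calibration_manual(1920, 1080, (0, 87), (1919, 1079), 125)
        tall_config.outside_image_is_na = False
        rows = [(0, np.nan, 500.0, 20.0)]
        out = eye_scroll_correct(gaze_session(rows), cal, tall_config)
        assert out.loc[0, "Corrected.Gaze.Y"] == 20 - 87  # negative, preserved

    def test_image_width_mismatch_is_hard_error(self, hd_calibration):
        config = CorrectionConfig(image_width=1000, image_height=5000)
        with pytest.raises(ConfigurationError, match="1000.*1920"):
            eye_scroll_correct(gaze_session([(0, np.nan, 1.0, 1.0)]),
                               hd_calibration, config)

    def test_output_file_written_and_loadable(self, sample_session, hd_calibration,
                                              tall_config, tmp_path):
        tall_config.output_file = str(tmp_path / "corrected.csv")
        out = eye_scroll_correct(sample_session, hd_calibration, tall_config)
        back = load_session(tall_config.output_file)
        assert "Scroll" in back.columns and "Timestamp.Shifted" in back.columns
        pd.testing.assert_frame_equal(back, out, check_dtype=False)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(150))
    def test_engine_matches_independent_replay(self, seed):
        syn, cal, config, bundles, rules = random_scenario(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fast = eye_scroll_correct(syn.session, cal, config, bundles, rules)
            slow = reference_oracle(syn.session, cal, config, bundles, rules)
        pd.testing.assert_frame_equal(fast, slow)
        max_scroll = cal.max_scroll(config.image_height)
        assert ((fast["Scroll"] >= 0) & (fast["Scroll"] <= max_scroll)).all()

    def test_empty_session_yields_empty_table(self, hd_calibration, tall_config):
        empty = gaze_session([])
        out = eye_scroll_correct(empty, hd_calibration, tall_config)
        assert len(out) == 0
        assert "Scroll" in out.columns

    def test_single_event_then_sample_hand_computed(self, hd_calibration):
        config = CorrectionConfig(image_width=1920, image_height=5000, scroll_lag=8.333)
        rows = [(100, wheel(960, 540, -120), np.nan, np.nan),
                (120, np.nan, 300.0, 400.0)]
        out = eye_scroll_correct(gaze_session(rows), hd_calibration, config)
        assert out.loc[1, "Corrected.Gaze.Y"] == 400 + 125
        oracle = reference_oracle(gaze_session(rows), hd_calibration, config)
        pd.testing.assert_frame_equal(out, oracle)


class TestAlgebraicProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_lag_equals_shifting_event_timestamps(self, seed):
        """Correcting with lag L == moving every event L ms later with lag 0."""
        rng = np.random.default_rng(seed)
        lag = 3.25  # offset from the 10 ms sample grid: no timestamp collisions
        cal = scroll_calibration_manual(400, 400, (0, 0), (399, 399), 50)
        samples = [(float(t), np.nan, float(rng.integers(0, 400)),
                    float(rng.integers(0, 400))) for t in range(0, 400, 10)]
        events = [(float(t), wheel(200, 200, int(rng.choice([-1, 1])) * 120),
                   np.nan, np.nan) for t in rng.choice(range(5, 395, 10), 8, replace=False)]
        config = CorrectionConfig(image_width=400, image_height=1200, scroll_lag=lag)

        lagged = gaze_session(sorted(samples + events))
        out_lag = eye_scroll_correct(lagged, cal, config)

        shifted_events = [(t + lag, d, x, y) for t, d, x, y in events]
        config0 = CorrectionConfig(image_width=400, image_height=1200, scroll_lag=0.0)
        out_shift = eye_scroll_correct(gaze_session(sorted(samples + shifted_events)),
                                       cal, config0)

        mask_a = out_lag["Gaze.X"].notna()
        mask_b = out_shift["Gaze.X"].notna()
        for col in ("Scroll", "Corrected.Gaze.X", "Corrected.Gaze.Y"):
            np.testing.assert_array_equal(out_lag.loc[mask_a, col].to_numpy(),
                                          out_shift.loc[mask_b, col].to_numpy())

    @pytest.mark.parametrize("seed", range(20))
    def test_concatenation_chains_through_starting_scroll(self, seed):
        """Correcting two halves with chained starting_scroll == one pass."""
        rng = np.random.default_rng(seed)
        cal = scroll_calibration_manual(400, 400, (0, 0), (399, 399), 50)
        config = CorrectionConfig(image_width=400, image_height=1500)

        def half(t0):
            samples = [(float(t0 + t), np.nan, float(rng.integers(0, 400)),
                        float(rng.integers(0, 400))) for t in range(0, 300, 10)]
            events = [(float(t0 + t), wheel(200, 200, int(rng.choice([-1, 1])) * 120),
                       np.nan, np.nan)
                      for t in rng.choice(range(5, 255, 10), 6, replace=False)]
            return gaze_session(sorted(samples + events))

        s1, s2 = half(0), half(1000)
        whole = eye_scroll_correct(pd.concat([s1, s2], ignore_index=True), cal, config)
        p1 = eye_scroll_correct(s1, cal, config)
        chained_cfg = CorrectionConfig(image_width=400, image_height=1500,
                                       starting_scroll=float(p1["Scroll"].iloc[-1]))
        p2 = eye_scroll_correct(s2, cal, chained_cfg)
        pd.testing.assert_frame_equal(
            whole.iloc[len(s1):].reset_index(drop=True), p2
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_x_of_uncaptured_points_only_translated(self, seed):
        syn, cal, config, _, _ = random_scenario(seed)
        config.outside_image_is_na = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = eye_scroll_correct(syn.session, cal, config)  # no fixed areas
        mask = out["Gaze.X"].notna()
        np.testing.assert_array_equal(
            out.loc[mask, "Corrected.Gaze.X"].to_numpy(),
            out.loc[mask, "Gaze.X"].to_numpy() - cal.viewport_top_left[0],
        )
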