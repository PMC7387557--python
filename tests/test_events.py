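"""Double-threshold event detection, rasters, and the dT death analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfluor.events import DetectionParams, build_raster, death_analysis, detect_events
from calfluor.exceptions import InsufficientDataError, ParameterError


def _deriv(values: list[float]) -> np.ndarray:
    """Derivative row with the conventional NaN at frame 0."""
    return np.array([[np.nan] + values])


PLAIN_SD = DetectionParams(robust=False)


class TestDetectEvents:
    def test_all_zero_derivative_gives_no_events(self):
        events = detect_events(_deriv([0.0] * 100))
        assert len(events) == 0
        assert list(events.columns) == ["roi_id", "frame", "time_s", "kind", "amplitude"]

    def test_single_positive_excursion_beats_both_thresholds(self):
        # 100 zeros + one 0.2: population SD ~= 0.0199, so the varying
        # threshold is 5 x 0.0199 ~= 0.0995 < 0.2 -> exactly one influx.
        series = [0.0] * 100 + [0.2]
        events = detect_events(_deriv(series), PLAIN_SD)
        assert len(events) == 1
        row = events.iloc[0]
        assert row["kind"] == "influx" and row["frame"] == 101
        assert row["amplitude"] == pytest.approx(0.2)
        assert 5 * np.std(np.array(series)) == pytest.approx(0.0995, abs=1e-3)

    def test_single_negative_excursion_is_efflux(self):
        # 200 zeros + one -0.3: theta_minus = -max(0.05, 5 x 0.0211) ~ -0.106.
        series = [0.0] * 200 + [-0.3]
        events = detect_events(_deriv(series), PLAIN_SD)
        assert len(events) == 1
        assert events.iloc[0]["kind"] == "efflux"
        assert events.iloc[0]["amplitude"] == pytest.approx(-0.3)

    def test_sub_static_excursion_ignored(self):
        events = detect_events(_deriv([0.0] * 100 + [0.04]))
        assert len(events) == 0  # below the 0.05 static cutoff

    def test_consecutive_frames_merge_to_extreme(self):
        series = [0.0] * 50 + [0.1, 0.3, 0.2] + [0.0] * 50
        merged = detect_events(_deriv(series), DetectionParams())
        assert len(merged) == 1
        assert merged.iloc[0]["frame"] == 52  # frame of the 0.3 extreme
        unmerged = detect_events(_deriv(series), DetectionParams(merge_consecutive=False))
        assert len(unmerged) == 3

    def test_amplitude_signs(self):
        series = [0.0] * 60 + [0.4] + [0.0] * 10 + [-0.5] + [0.0] * 60
        events = detect_events(_deriv(series))
        influx = events[events["kind"] == "influx"]
        efflux = events[events["kind"] == "efflux"]
        assert (influx["amplitude"] > 0).all() and (efflux["amplitude"] < 0).all()

    def test_static_threshold_in_per_frame_units(self):
        # deriv of 0.0008/s over 600-s frames is 0.48 per frame: detected
        # under per-frame units, invisible under per-second units.
        series = [0.0] * 100 + [0.0008]
        per_frame = detect_events(_deriv(series), frame_period_s=600.0)
        assert len(per_frame) == 1
        per_second = detect_events(
            _deriv(series),
            DetectionParams(threshold_units="second", robust=True),
            frame_period_s=600.0,
        )
        assert len(per_second) == 0

    def test_lenient_negative_mode_admits_smaller_effluxes(self):
        series = [0.0] * 30 + [0.5, 0.0, 0.5, 0.0, 0.5] + [-0.08] + [0.0] * 30
        strict = detect_events(_deriv(series), DetectionParams(robust=False))
        lenient = detect_events(
            _deriv(series), DetectionParams(robust=False, negative_mode="lenient")
        )
        n_eff = lambda ev: (ev["kind"] == "efflux").sum()
        assert n_eff(lenient) > n_eff(strict)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            detect_events(_deriv([0.1, 0.2]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=10, max_size=80), st.booleans())
    def test_doubling_sd_multiplier_never_adds_events(self, series, robust):
        base = detect_events(_deriv(series), DetectionParams(robust=robust))
        doubled = detect_events(
            _deriv(series), DetectionParams(sd_multiplier=10.0, robust=robust)
        )
        assert len(doubled) <= len(base)

    def test_detection_is_deterministic(self, rng):
        deriv = np.concatenate([[np.nan], rng.normal(0, 0.02, 120)])[None, :]
        a = detect_events(deriv)
        b = detect_events(deriv)
        assert a.equals(b)


class TestBuildRaster:
    def test_empty_table(self):
        events = pd.DataFrame(columns=["roi_id", "frame", "time_s", "kind", "amplitude"])
        raster = build_raster(events, n_rois=4, n_frames=10)
        assert raster.raster.sum() == 0 and raster.raster.shape == (4, 10)

    def test_single_influx_and_efflux_exclusion(self):
        events = pd.DataFrame(
            [
                {"roi_id": 3, "frame": 5, "time_s": 5.0, "kind": "influx", "amplitude": 0.2},
                {"roi_id": 3, "frame": 8, "time_s": 8.0, "kind": "efflux", "amplitude": -0.2},
            ]
        )
        raster = build_raster(events, n_rois=4, n_frames=10)
        assert raster.raster.sum() == 1
        assert raster.raster[2, 5] == 1  # roi 3 -> row index 2

    def test_out_of_range_indices(self):
        events = pd.DataFrame(
            [{"roi_id": 9, "frame": 5, "time_s": 5.0, "kind": "influx", "amplitude": 0.2}]
        )
        with pytest.raises(ParameterError):
            build_raster(events, n_rois=4, n_frames=10)


class TestDeathAnalysis:
    @staticmethod
    def _event(roi, frame, kind, period=600.0):
        return {
            "roi_id": roi,
            "frame": frame,
            "time_s": frame * period,
            "kind": kind,
            "amplitude": 0.5 if kind == "influx" else -0.5,
        }

    def test_single_spike_dt_five_hours(self):
        events = pd.DataFrame(
            [self._event(1, 10, "influx"), self._event(1, 40, "efflux")]
        )
        table, hists = death_analysis(events, frame_period_s=600.0, n_frames=61)
        assert len(table) == 1
        assert table.iloc[0]["dt_s"] == 30 * 600.0  # 5 h
        counts, edges = hists["dt_s"]
        assert counts[np.digitize(30 * 600.0, edges) - 1] == 1

    def test_multiple_influxes_excluded(self):
        events = pd.DataFrame(
            [
                self._event(1, 5, "influx"),
                self._event(1, 10, "influx"),
                self._event(1, 40, "efflux"),
            ]
        )
        table, _ = death_analysis(events, 600.0)
        assert len(table) == 0

    def test_efflux_before_influx_excluded(self):
        events = pd.DataFrame(
            [self._event(1, 40, "influx"), self._event(1, 10, "efflux")]
        )
        table, _ = death_analysis(events, 600.0)
        assert len(table) == 0

    def test_empty_events_give_empty_records(self):
        events = pd.DataFrame(columns=["roi_id", "frame", "time_s", "kind", "amplitude"])
        table, hists = death_analysis(events, 600.0)
        assert len(table) == 0 and hists["dt_s"][0].sum() == 0
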