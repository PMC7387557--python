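"""Double-threshold calcium influx/efflux detection, rasters, and ΔT analysis.

Detection operates on the per-ROI derivative of the background-normalized
trace. For each ROI a spread estimate s of the derivative series combines
with a static cutoff into a double threshold

    theta_plus  = max(static_threshold, sd_multiplier * s)
    theta_minus = -theta_plus                      (strict reading)

Frames with derivative above theta_plus are influx candidates; below
theta_minus, efflux candidates. Runs of consecutive same-kind candidate
frames merge into one event timed at the frame of extreme derivative,
whose value is the event amplitude.

The static cutoff (default 0.05) is interpreted in per-frame units
(dimensionless change of F_star per frame), so the same number applies to
1-s and 600-s frame periods; a ``threshold_units="second"`` switch treats
it as 1/s instead.

The spread estimate defaults to the scaled median absolute deviation
(1.4826 x MAD), which estimates the noise level of the derivative without
being inflated by the transients themselves; the plain whole-trace standard
deviation (population, ddof=0) is available with ``robust=False`` but can
self-mask dense or large events (a recording whose spikes dominate the SD
raises its own threshold above them).

The cell-death analysis selects ROIs with exactly one influx and exactly
one efflux, influx first, and reports the delay dT between them — the
single-spike influx-then-efflux signature of a dying cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "DetectionParams",
    "SpikeRaster",
    "detect_events",
    "build_raster",
    "death_analysis",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["roi_id", "frame", "time_s", "kind", "amplitude"]
DEATH_COLUMNS = ["roi_id", "influx_frame", "efflux_frame", "dt_s"]


@dataclass(frozen=True)
class DetectionParams:
    """Double-threshold detection parameters.

    static_threshold: fixed cutoff on |derivative| (per-frame units by
    default). sd_multiplier: factor on the per-ROI spread estimate.
    robust: use 1.4826 x MAD instead of the whole-trace SD.
    negative_mode: "strict" uses theta_minus = -max(static, k s) (parallel
    to the positive side); "lenient" uses -min(static, k s).
    """

    static_threshold: float = 0.05
    sd_multiplier: float = 5.0
    sd_scope: str = "whole_trace"
    merge_consecutive: bool = True
    robust: bool = True
    threshold_units: str = "frame"
    negative_mode: str = "strict"

    def __post_init__(self) -> None:
        if not (self.static_threshold > 0):
            raise ParameterError("static_threshold must be > 0")
        if not (self.sd_multiplier > 0):
            raise ParameterError("sd_multiplier must be > 0")
        if self.sd_scope != "whole_trace":
            raise ParameterError("sd_scope must be 'whole_trace'")
        if self.threshold_units not in ("frame", "second"):
            raise ParameterError("threshold_units must be 'frame' or 'second'")
        if self.negative_mode not in ("strict", "lenient"):
            raise ParameterError("negative_mode must be 'strict' or 'lenient'")


@dataclass
class SpikeRaster:
    """Binary influx raster: raster[r, f] = 1 iff ROI r+1 has an influx at frame f."""

    raster: np.ndarray  # (n_rois, n_frames) uint8
    frame_period_s: float
    start_time_s: float = 0.0

    @property
    def n_rois(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Raster as a DataFrame with frame times as column labels."""
        times = self.start_time_s + np.arange(self.n_frames) * self.frame_period_s
        return pd.DataFrame(
            self.raster, index=np.arange(1, self.n_rois + 1), columns=times
        )


def _spread(values: np.ndarray, robust: bool) -> float:
    if robust:
        med = np.median(values)
        return float(1.4826 * np.median(np.abs(values - med)))
    return float(np.std(values))  # population SD, ddof=0


def _runs(candidates: np.ndarray) -> list[np.ndarray]:
    """Split sorted candidate indices into runs of consecutive values."""
    if candidates.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(candidates) > 1)
    return np.split(candidates, breaks + 1)


def detect_events(
    deriv: np.ndarray,
    params: DetectionParams | None = None,
    frame_period_s: float = 1.0,
    roi_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Detect influx/efflux events from per-ROI derivative traces.

    ``deriv``: (n_rois, n_frames) in 1/s, NaN allowed at frame 0 (as
    produced by :func:`calfluor.fluorometry.normalize`). Returns a
    DataFrame with columns roi_id, frame, time_s, kind ("influx"/"efflux"),
    amplitude (the extreme derivative value, 1/s).
    """
    params = params or DetectionParams()
    deriv = np.atleast_2d(np.asarray(deriv, dtype=np.float64))
    if roi_ids is None:
        roi_ids = np.arange(1, deriv.shape[0] + 1)

    # thresholds are applied in per-frame units unless configured otherwise
    scale = frame_period_s if params.threshold_units == "frame" else 1.0
    records: list[dict] = []
    for i, roi in enumerate(roi_ids):
        series = deriv[i]
        valid = np.flatnonzero(~np.isnan(series))
        if valid.size < 3:
            raise InsufficientDataError(
                f"ROI {roi}: only {valid.size} derivative samples; need >= 3"
            )
        working = series[valid] * scale
        s = _spread(working, params.robust)
        theta_plus = max(params.static_threshold, params.sd_multiplier * s)
        if params.negative_mode == "strict":
            theta_minus = -theta_plus
        else:
            theta_minus = -min(params.static_threshold, params.sd_multiplier * s)

        for kind, candidates in (
            ("influx", valid[working > theta_plus]),
            ("efflux", valid[working < theta_minus]),
        ):
            groups = _runs(candidates) if params.merge_consecutive else [
                np.array([c]) for c in candidates
            ]
            for run in groups:
                vals = series[run]
                extreme = run[int(np.argmax(vals))] if kind == "influx" else run[
                    int(np.argmin(vals))
                ]
                records.append(
                    {
                        "roi_id": int(roi),
                        "frame": int(extreme),
                        "time_s": float(extreme * frame_period_s),
                        "kind": kind,
                        "amplitude": float(series[extreme]),
                    }
                )
    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    return events.sort_values(["roi_id", "frame", "kind"], ignore_index=True)


def build_raster(
    events: pd.DataFrame, n_rois: int, n_frames: int, frame_period_s: float = 1.0
) -> SpikeRaster:
    """Binary influx raster from an event table; efflux events are excluded."""
    raster = np.zeros((n_rois, n_frames), dtype=np.uint8)
    influx = events[events["kind"] == "influx"]
    rois = influx["roi_id"].to_numpy(dtype=int)
    frames = influx["frame"].to_numpy(dtype=int)
    if rois.size:
        if rois.min() < 1 or rois.max() > n_rois:
            raise ParameterError("event roi_id outside 1..n_rois")
        if frames.min() < 0 or frames.max() >= n_frames:
            raise ParameterError("event frame outside 0..n_frames-1")
        raster[rois - 1, frames] = 1
    return SpikeRaster(raster=raster, frame_period_s=frame_period_s)


def death_analysis(
    events: pd.DataFrame,
    frame_period_s: float,
    hist_bin_width_s: float = 3600.0,
    n_frames: int | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Single-spike cell-death records and timing histograms.

    Selects ROIs with exactly one influx and exactly one efflux event where
    the influx precedes the efflux; dT_s = (efflux_frame - influx_frame) x
    frame period. Returns (records, histograms) where histograms maps
    "influx_time_s" / "efflux_time_s" / "dt_s" to (counts, bin_edges) with
    the given bin width (default 1 h, suited to the 10-h regime).
    """
    if not (hist_bin_width_s > 0):
        raise ParameterError("hist_bin_width_s must be > 0")
    records = []
    if len(events):
        for roi, group in events.groupby("roi_id"):
            influx = group[group["kind"] == "influx"]
            efflux = group[group["kind"] == "efflux"]
            if len(influx) == 1 and len(efflux) == 1:
                f_in = int(influx["frame"].iloc[0])
                f_out = int(efflux["frame"].iloc[0])
                if f_in < f_out:
                    records.append(
                        {
                            "roi_id": int(roi),
                            "influx_frame": f_in,
                            "efflux_frame": f_out,
                            "dt_s": (f_out - f_in) * frame_period_s,
                        }
                    )
    table = pd.DataFrame(records, columns=DEATH_COLUMNS)

    if n_frames is not None:
        t_max = n_frames * frame_period_s
    elif len(events):
        t_max = float(events["time_s"].max()) + frame_period_s
    else:
        t_max = hist_bin_width_s
    edges = np.arange(0.0, t_max + hist_bin_width_s, hist_bin_width_s)
    histograms = {}
    for name, values in (
        ("influx_time_s", table["influx_frame"].to_numpy() * frame_period_s),
        ("efflux_time_s", table["efflux_frame"].to_numpy() * frame_period_s),
        ("dt_s", table["dt_s"].to_numpy()),
    ):
        counts, _ = np.histogram(values, bins=edges)
        histograms[name] = (counts, edges)
    return table, histograms
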