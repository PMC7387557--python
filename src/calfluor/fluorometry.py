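"""Per-ROI fluorescence traces and their normalizations.

For each ROI the mean intensity over its pixels is computed per frame,

    F_mean(t) = sum_i F_pixel_i(t) / n ,

together with a per-frame background trace F_bkg(t) (mean over the
background mask). Two normalizations follow:

    F_star(t) = F_mean(t) / F_bkg(t)                 (background ratio)
    F_rel(t)  = (F_mean(t) - F_bkg(t)) / F_max       (relative fluorescence)

where F_max is the global maximum of the ROI-mean traces over the whole
recording (an ROI-level quantity; a configurable raw-pixel variant exists
so a single hot pixel cannot rescale every trace). Because the background
is per-frame, slow multiplicative photobleaching cancels in F_star.

Event detection operates on the backward difference of F_star,

    deriv(t) = (F_star(t) - F_star(t-1)) / dt ,   t >= 1  [1/s]

stored with NaN at t = 0; an event detected at derivative index t carries
that frame's timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NormalizationError, ParameterError, ShapeError
from .io import Movie
from .segment import ROISet

__all__ = ["TraceSet", "mean_roi_intensity", "background_trace", "normalize", "compute_traces"]


@dataclass
class TraceSet:
    """Per-ROI fluorescence time series and normalizations.

    Arrays ``f_mean``, ``f_star``, ``f_rel``, ``deriv`` have shape
    (n_rois, n_frames); ``f_bkg`` has shape (n_frames,). ``deriv`` is in
    1/s with NaN at frame 0. ``roi_ids`` are the 1-based ROI labels.
    """

    f_mean: np.ndarray
    f_bkg: np.ndarray
    f_star: np.ndarray
    f_rel: np.ndarray
    f_max: float
    deriv: np.ndarray
    frame_period_s: float
    roi_ids: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.f_mean.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f_mean.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_s

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per ROI x frame."""
        rows = []
        times = self.times_s
        for i, roi in enumerate(self.roi_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "roi_id": int(roi),
                        "frame": np.arange(self.n_frames),
                        "time_s": times,
                        "F_mean": self.f_mean[i],
                        "F_bkg": self.f_bkg,
                        "F_star": self.f_star[i],
                        "F_rel": self.f_rel[i],
                        "deriv": self.deriv[i],
                    }
                )
            )
        columns = ["roi_id", "frame", "time_s", "F_mean", "F_bkg", "F_star", "F_rel", "deriv"]
        if not rows:
            return pd.DataFrame(columns=columns)
        return pd.concat(rows, ignore_index=True)[columns]


def mean_roi_intensity(movie: Movie, rois: ROISet) -> np.ndarray:
    """Mean pixel intensity per ROI per frame, shape (n_rois, n_frames)."""
    if rois.n_rois == 0:
        raise ParameterError("ROISet is empty; nothing to extract")
    if rois.label_image.shape != movie.shape:
        raise ShapeError(
            f"label image shape {rois.label_image.shape} != frame shape {movie.shape}"
        )
    labels = rois.label_image
    k = rois.n_rois
    frames = movie.frames.reshape(movie.n_frames, -1).astype(np.float64)
    flat_labels = labels.ravel()
    sums = np.zeros((k, movie.n_frames))
    for roi in range(1, k + 1):
        idx = np.flatnonzero(flat_labels == roi)
        sums[roi - 1] = frames[:, idx].mean(axis=1)
    return sums


def background_trace(movie: Movie, rois: ROISet) -> np.ndarray:
    """Mean intensity of the background-mask pixels per frame, shape (n_frames,)."""
    if rois.background_mask.shape != movie.shape:
        raise ShapeError(
            f"background mask shape {rois.background_mask.shape} != frame shape {movie.shape}"
        )
    idx = np.flatnonzero(rois.background_mask.ravel())
    if idx.size == 0:
        raise ConfigurationError(
            "background mask is empty; supply a background ROI or reduce bg_dilation_px"
        )
    frames = movie.frames.reshape(movie.n_frames, -1).astype(np.float64)
    return frames[:, idx].mean(axis=1)


def normalize(
    f_mean: np.ndarray,
    f_bkg: np.ndarray,
    frame_period_s: float,
    roi_ids: np.ndarray | None = None,
    f_max_mode: str = "roi_mean",
) -> TraceSet:
    """Compute F_star, F_rel, F_max and the derivative from raw traces.

    ``f_max_mode``: "roi_mean" (default) takes F_max as the maximum of the
    ROI-mean traces; "raw" lets the caller pass a precomputed pixel maximum
    via ``f_max_mode=("raw", value)``.
    """
    f_mean = np.atleast_2d(np.asarray(f_mean, dtype=np.float64))
    f_bkg = np.asarray(f_bkg, dtype=np.float64)
    if f_bkg.shape != (f_mean.shape[1],):
        raise ShapeError(
            f"f_bkg has shape {f_bkg.shape}; expected ({f_mean.shape[1]},)"
        )
    if not (frame_period_s > 0):
        raise ParameterError("frame_period_s must be > 0")
    bad = np.flatnonzero(f_bkg <= 0)
    if bad.size:
        raise NormalizationError(f"background trace <= 0 at frame {int(bad[0])}")

    if isinstance(f_max_mode, tuple) and f_max_mode[0] == "raw":
        f_max = float(f_max_mode[1])
    else:
        f_max = float(f_mean.max())
    f_star = f_mean / f_bkg[None, :]
    f_rel = (f_mean - f_bkg[None, :]) / f_max if f_max > 0 else np.zeros_like(f_mean)
    deriv = np.full_like(f_star, np.nan)
    deriv[:, 1:] = np.diff(f_star, axis=1) / frame_period_s
    if roi_ids is None:
        roi_ids = np.arange(1, f_mean.shape[0] + 1)
    return TraceSet(
        f_mean=f_mean,
        f_bkg=f_bkg,
        f_star=f_star,
        f_rel=f_rel,
        f_max=f_max,
        deriv=deriv,
        frame_period_s=frame_period_s,
        roi_ids=np.asarray(roi_ids),
    )


def compute_traces(movie: Movie, rois: ROISet, f_max_mode: str = "roi_mean") -> TraceSet:
    """Extract raw and normalized traces for all ROIs of a movie."""
    f_mean = mean_roi_intensity(movie, rois)
    f_bkg = background_trace(movie, rois)
    return normalize(f_mean, f_bkg, movie.frame_period_s, rois.roi_ids, f_max_mode)
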