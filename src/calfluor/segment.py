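"""Automated cell-body segmentation.

Pipeline: temporal maximum-intensity projection of the movie; Gaussian
smoothing; global Otsu threshold; 8-connected components; area filtering;
consecutive relabeling. Centroids are computed on the projection-intensity-
weighted mask. The background region used for the background fluorescence
trace is the complement of all ROIs dilated by ``bg_dilation_px``.

The algorithm is deliberately the simplest adequate one for bright,
well-separated somata on a dark background; every constant is exposed in
:class:`SegmentationConfig`. A blank or constant movie yields zero ROIs
with a logged warning rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .exceptions import ParameterError, ShapeError
from .io import Movie

logger = logging.getLogger(__name__)

__all__ = ["SegmentationConfig", "ROISet", "segment_cells", "manual_rois"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable constants of the segmentation pipeline (pixel units)."""

    sigma_smooth_px: float = 2.0
    area_min_px: int = 30
    area_max_px: int = 2000
    bg_dilation_px: int = 5

    def __post_init__(self) -> None:
        if self.sigma_smooth_px < 0:
            raise ParameterError("sigma_smooth_px must be >= 0")
        if not (0 < self.area_min_px <= self.area_max_px):
            raise ParameterError("need 0 < area_min_px <= area_max_px")
        if self.bg_dilation_px < 0:
            raise ParameterError("bg_dilation_px must be >= 0")


@dataclass
class ROISet:
    """Labeled cell-body masks with per-ROI areas and centroids.

    ``label_image``: 0 = background, k in 1..K = ROI k (consecutive,
    pairwise disjoint by construction). ``areas[k-1]`` is the pixel count n
    of ROI k; ``centroids[k-1]`` its (row, col) centroid as reals.
    ``background_mask`` marks the pixels used for the background trace; it
    is disjoint from every dilated ROI.
    """

    label_image: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        labels = np.unique(self.label_image)
        labels = labels[labels > 0]
        expected = np.arange(1, self.n_rois + 1)
        if not np.array_equal(labels, expected[: labels.size]) or labels.size != self.n_rois:
            raise ParameterError("ROI labels must be consecutive 1..K")

    @property
    def n_rois(self) -> int:
        return int(self.areas.shape[0])

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(1, self.n_rois + 1)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.label_image == roi_id

    def write(self, path: str | Path) -> Path:
        """Write the label image as a 16-bit TIFF."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, self.label_image.astype(np.uint16))
        return path


def _finalize(
    labels: np.ndarray,
    intensity: np.ndarray | None,
    bg_dilation_px: int,
) -> ROISet:
    """Relabel consecutively, compute areas/centroids, build the background mask."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    relabeled = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        relabeled[labels == old] = new
    k = ids.size
    areas = np.bincount(relabeled.ravel(), minlength=k + 1)[1:].astype(np.int64)
    if k:
        weights = np.ones_like(relabeled, dtype=np.float64) if intensity is None else np.asarray(
            intensity, dtype=np.float64
        )
        centroids = np.array(
            ndimage.center_of_mass(weights, labels=relabeled, index=np.arange(1, k + 1))
        )
    else:
        centroids = np.zeros((0, 2))
    fg = relabeled > 0
    if bg_dilation_px > 0:
        fg = ndimage.binary_dilation(fg, structure=disk(bg_dilation_px))
    return ROISet(
        label_image=relabeled,
        areas=areas,
        centroids=centroids,
        background_mask=~fg,
    )


def segment_cells(movie: Movie, config: SegmentationConfig | None = None) -> ROISet:
    """Segment cell bodies from a movie's maximum-intensity projection.

    Invariant to frame order (the projection is permutation-invariant).
    Components with area outside [area_min_px, area_max_px] are discarded.
    """
    config = config or SegmentationConfig()
    projection = movie.frames.max(axis=0).astype(np.float64)
    if projection.max() == projection.min():
        logger.warning("constant maximum projection: returning 0 ROIs")
        empty = np.zeros(projection.shape, dtype=np.int32)
        return _finalize(empty, projection, config.bg_dilation_px)
    smoothed = (
        gaussian(projection, sigma=config.sigma_smooth_px, preserve_range=True)
        if config.sigma_smooth_px > 0
        else projection
    )
    threshold = threshold_otsu(smoothed)
    binary = smoothed > threshold
    labels = cc_label(binary, connectivity=2)  # 8-connectivity
    areas = np.bincount(labels.ravel())
    for roi_id in range(1, labels.max() + 1):
        if not (config.area_min_px <= areas[roi_id] <= config.area_max_px):
            labels[labels == roi_id] = 0
    return _finalize(labels, projection, config.bg_dilation_px)


def manual_rois(
    mask_image: np.ndarray,
    movie_shape: tuple[int, int] | None = None,
    bg_dilation_px: int = 5,
) -> ROISet:
    """Wrap user-provided masks (labeled or binary) into an ROISet.

    Binary masks are connected-component labeled (8-connectivity); labeled
    masks keep their regions (relabeled consecutively). No area filtering is
    applied — the user's selection is taken as-is.
    """
    mask_image = np.asarray(mask_image)
    if mask_image.ndim != 2:
        raise ShapeError(f"mask must be 2-D; got shape {mask_image.shape}")
    if movie_shape is not None and tuple(mask_image.shape) != tuple(movie_shape):
        raise ShapeError(
            f"mask shape {mask_image.shape} does not match movie frame shape {movie_shape}"
        )
    unique = np.unique(mask_image)
    if unique.size <= 2 and unique.max(initial=0) <= 1:
        labels = cc_label(mask_image > 0, connectivity=2)
    else:
        labels = mask_image.astype(np.int32)
    return _finalize(labels, None, bg_dilation_px)
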