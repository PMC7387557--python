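"""Recovery scoring of pipeline output against synthetic ground truth.

Matches detected ROIs to ground-truth cells (greedy best-IoU matching),
scores influx detection as precision/recall/F1 with a frame tolerance, and
scores recovered cell-death records against ground-truth (influx, efflux)
frames. Used by the test suite and the acceptance script; useful for any
parameter study on simulated recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import ROISet

__all__ = ["RoiMatch", "match_rois", "spike_scores", "death_recovery", "measure_patch_snr"]


@dataclass
class RoiMatch:
    """Greedy IoU matching of detected ROIs to ground-truth cells.

    ``cell_to_roi`` maps 0-based ground-truth cell index -> detected ROI id
    (1-based) for matches with IoU >= the threshold.
    """

    cell_to_roi: dict[int, int]
    precision: float
    recall: float
    n_cells: int
    n_rois: int


def match_rois(gt_masks: np.ndarray, rois: ROISet, iou_threshold: float = 0.3) -> RoiMatch:
    """Match detected ROIs to ground-truth labeled masks by best IoU."""
    gt_ids = np.unique(gt_masks)
    gt_ids = gt_ids[gt_ids > 0]
    pairs = []
    for gi in gt_ids:
        gmask = gt_masks == gi
        overlapping = np.unique(rois.label_image[gmask])
        for ri in overlapping[overlapping > 0]:
            rmask = rois.label_image == ri
            inter = np.logical_and(gmask, rmask).sum()
            union = np.logical_or(gmask, rmask).sum()
            iou = inter / union if union else 0.0
            if iou >= iou_threshold:
                pairs.append((iou, int(gi), int(ri)))
    pairs.sort(reverse=True)
    cell_to_roi: dict[int, int] = {}
    used_rois: set[int] = set()
    for _, gi, ri in pairs:
        if (gi - 1) not in cell_to_roi and ri not in used_rois:
            cell_to_roi[gi - 1] = ri
            used_rois.add(ri)
    n_cells, n_rois = gt_ids.size, rois.n_rois
    recall = len(cell_to_roi) / n_cells if n_cells else 1.0
    precision = len(cell_to_roi) / n_rois if n_rois else 1.0
    return RoiMatch(cell_to_roi, precision, recall, int(n_cells), int(n_rois))


def _match_frames(gt_frames: list[int], det_frames: list[int], tol: int) -> int:
    """Count of one-to-one matches within +/- tol frames (greedy on sorted lists)."""
    matched = 0
    available = sorted(det_frames)
    for g in sorted(gt_frames):
        for i, d in enumerate(available):
            if abs(d - g) <= tol:
                matched += 1
                del available[i]
                break
    return matched


def spike_scores(
    gt_spike_times: list[list[int]],
    events: pd.DataFrame,
    match: RoiMatch,
    tol_frames: int = 1,
) -> dict[str, float]:
    """Influx-detection precision/recall/F1 vs ground-truth onsets.

    Detected influx frames of each matched ROI are compared to the true
    onset frames of its cell with a +/- tol_frames tolerance. Unmatched
    cells contribute misses; influxes of unmatched ROIs count as false
    positives.
    """
    influx = events[events["kind"] == "influx"]
    by_roi = {int(r): g["frame"].tolist() for r, g in influx.groupby("roi_id")}
    tp = 0
    n_gt = sum(len(t) for t in gt_spike_times)
    n_det = len(influx)
    for cell, train in enumerate(gt_spike_times):
        roi = match.cell_to_roi.get(cell)
        if roi is None:
            continue
        tp += _match_frames(train, by_roi.get(roi, []), tol_frames)
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_gt if n_gt else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "n_gt": n_gt, "n_det": n_det}


def death_recovery(
    gt_death_events: list[tuple[int, int] | None],
    death_table: pd.DataFrame,
    match: RoiMatch,
    frame_period_s: float,
    tol_frames: int = 1,
) -> dict[str, float]:
    """Fraction of dying cells recovered with influx/efflux within tolerance.

    A dying cell counts as recovered when its matched ROI has a death
    record whose influx and efflux frames are each within +/- tol_frames of
    ground truth. Also reports the maximum |dT error| in frames over the
    recovered cells.
    """
    by_roi = {int(r["roi_id"]): r for _, r in death_table.iterrows()}
    n_dying = sum(1 for ev in gt_death_events if ev is not None)
    recovered = 0
    dt_errors = []
    for cell, ev in enumerate(gt_death_events):
        if ev is None:
            continue
        roi = match.cell_to_roi.get(cell)
        rec = by_roi.get(roi) if roi is not None else None
        if rec is None:
            continue
        gt_in, gt_out = ev
        if abs(rec["influx_frame"] - gt_in) <= tol_frames and abs(
            rec["efflux_frame"] - gt_out
        ) <= tol_frames:
            recovered += 1
            gt_dt = (gt_out - gt_in) * frame_period_s
            dt_errors.append(abs(rec["dt_s"] - gt_dt) / frame_period_s)
    fraction = recovered / n_dying if n_dying else 1.0
    return {
        "fraction_recovered": fraction,
        "n_dying": n_dying,
        "n_recovered": recovered,
        "max_dt_error_frames": max(dt_errors) if dt_errors else 0.0,
    }


def measure_patch_snr(
    movie_frames: np.ndarray,
    centers: list[tuple[int, int]],
    size: int = 43,
    frame_pair: tuple[int, int] = (0, 1),
) -> float:
    """Median pairwise patch SNR (dB) between two frames of a movie.

    Extracts same-center patches from two frames and reports the median
    SNR over centers — the noise level a patch-comparison protocol sees on
    this recording.
    """
    from .quality import extract_patches, snr

    half = size // 2 + 1
    h, w = movie_frames.shape[1:]
    safe = [c for c in centers if half <= c[0] < h - half and half <= c[1] < w - half]
    a = extract_patches(movie_frames[frame_pair[0]], safe, size)
    b = extract_patches(movie_frames[frame_pair[1]], safe, size)
    return float(np.median([snr(x, y) for x, y in zip(a, b)]))
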