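"""Sørensen-Dice spike-train synchrony and connectivity-map network analysis.

Influx spike trains (binary rasters) are optionally binned (a bin is
occupied if it contains any influx); for two trains a, b viewed as sets of
occupied bins the Sørensen-Dice coefficient is

    Dice(a, b) = 2 |a ∩ b| / (|a| + |b|)  in [0, 1],

1 for identical nonempty trains, 0 for disjoint ones. Pairs with
|a| + |b| = 0 are undefined and stored as 0 with a flag.

The connectivity map is an undirected graph with vertices at ROI centroids
and an edge (i, j) iff both ROIs are active (>= 1 influx in the session)
and Dice(i, j) >= an edge threshold. Session metrics are the number of
active ROIs, the edge count, and edges per active ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ParameterError, ShapeError
from .events import SpikeRaster
from .segment import ROISet

__all__ = [
    "DiceMatrix",
    "NetworkMetrics",
    "dice_matrix",
    "build_graph",
    "metrics",
    "session_series",
]


@dataclass
class DiceMatrix:
    """Symmetric K x K Dice coefficients between binned influx trains.

    ``defined[i, j]`` is False where both trains are empty (value stored
    as 0). Diagonal is 1 for ROIs with >= 1 spike, 0 (undefined) for
    silent ROIs.
    """

    values: np.ndarray
    defined: np.ndarray
    bin_width_frames: int


@dataclass
class NetworkMetrics:
    """Per-session network activity summary."""

    n_active: int
    n_edges: int
    edges_per_active: float
    edges_per_active_defined: bool  # False when n_active == 0


def _bin_raster(raster: np.ndarray, bin_width_frames: int) -> np.ndarray:
    if bin_width_frames == 1:
        return raster.astype(bool)
    k, t = raster.shape
    n_bins = -(-t // bin_width_frames)
    padded = np.zeros((k, n_bins * bin_width_frames), dtype=bool)
    padded[:, :t] = raster > 0
    return padded.reshape(k, n_bins, bin_width_frames).any(axis=2)


def dice_matrix(raster: SpikeRaster | np.ndarray, bin_width_frames: int = 1) -> DiceMatrix:
    """Pairwise Sørensen-Dice coefficients of binned influx trains."""
    if bin_width_frames < 1:
        raise ParameterError("bin_width_frames must be >= 1")
    arr = raster.raster if isinstance(raster, SpikeRaster) else np.asarray(raster)
    if arr.ndim != 2:
        raise ShapeError(f"raster must be 2-D (rois x frames); got shape {arr.shape}")
    binned = _bin_raster(arr, bin_width_frames).astype(np.float64)
    counts = binned.sum(axis=1)
    inter = binned @ binned.T
    denom = counts[:, None] + counts[None, :]
    defined = denom > 0
    values = np.zeros_like(inter)
    np.divide(2.0 * inter, denom, out=values, where=defined)
    return DiceMatrix(values=values, defined=defined, bin_width_frames=bin_width_frames)


def build_graph(
    dice: DiceMatrix,
    rois: ROISet,
    raster: SpikeRaster | np.ndarray,
    edge_threshold: float = 0.5,
    session_label: str | None = None,
) -> nx.Graph:
    """Spatial connectivity map: ROI-centroid vertices, supra-threshold Dice edges.

    Edge (i, j) exists iff i != j, both ROIs have >= 1 influx in the
    session, and Dice(i, j) >= edge_threshold; the Dice value is carried as
    the edge weight attribute ``dice``.
    """
    if not (0 <= edge_threshold <= 1):
        raise ParameterError(f"edge_threshold must be in [0, 1]; got {edge_threshold}")
    arr = raster.raster if isinstance(raster, SpikeRaster) else np.asarray(raster)
    k = dice.values.shape[0]
    if arr.shape[0] != k or rois.n_rois != k:
        raise ShapeError("Dice matrix, raster and ROISet disagree on the number of ROIs")
    active = arr.sum(axis=1) > 0
    graph = nx.Graph()
    if session_label is not None:
        graph.graph["session"] = session_label
    for i in range(k):
        graph.add_node(
            i + 1,
            y=float(rois.centroids[i, 0]),
            x=float(rois.centroids[i, 1]),
            active=bool(active[i]),
        )
    for i in range(k):
        for j in range(i + 1, k):
            if active[i] and active[j] and dice.values[i, j] >= edge_threshold:
                graph.add_edge(i + 1, j + 1, dice=float(dice.values[i, j]))
    return graph


def metrics(graph: nx.Graph, raster: SpikeRaster | np.ndarray | None = None) -> NetworkMetrics:
    """Active-ROI count, edge count, and edges per active ROI."""
    if raster is not None:
        arr = raster.raster if isinstance(raster, SpikeRaster) else np.asarray(raster)
        n_active = int((arr.sum(axis=1) > 0).sum())
    else:
        n_active = sum(1 for _, data in graph.nodes(data=True) if data.get("active"))
    n_edges = graph.number_of_edges()
    if n_active > 0:
        return NetworkMetrics(n_active, n_edges, n_edges / n_active, True)
    return NetworkMetrics(0, n_edges, 0.0, False)


def session_series(
    movies: list,
    session_times_h: list[float] | None = None,
    segmentation_config=None,
    detection_params=None,
    edge_threshold: float = 0.5,
    bin_width_frames: int = 1,
    rois: ROISet | None = None,
    resegment_each: bool = False,
) -> tuple[pd.DataFrame, list[nx.Graph]]:
    """Run segmentation -> traces -> detection -> graph over an ordered
    list of session movies and tabulate network metrics per session.

    ROIs are segmented once on the first session and reused (vertices
    comparable over time) unless ``resegment_each`` is set. Returns a
    metrics table with per-session n_active / n_edges / edges_per_active
    and the percent change of the edge count between consecutive sessions,
    plus the per-session graphs.
    """
    from .events import build_raster, detect_events
    from .fluorometry import compute_traces
    from .segment import segment_cells

    if not movies:
        raise ParameterError("at least one session movie is required")
    shape = movies[0].shape
    for m in movies[1:]:
        if m.shape != shape:
            raise ShapeError(f"session frame shapes differ: {m.shape} vs {shape}")
    if session_times_h is None:
        session_times_h = list(range(len(movies)))
    if len(session_times_h) != len(movies):
        raise ParameterError("session_times_h length must match the number of movies")

    shared_rois = rois
    rows = []
    graphs: list[nx.Graph] = []
    for t_h, movie in zip(session_times_h, movies):
        if resegment_each or shared_rois is None:
            current = segment_cells(movie, segmentation_config)
            if not resegment_each:
                shared_rois = current
        else:
            current = shared_rois
        traces = compute_traces(movie, current)
        events = detect_events(
            traces.deriv, detection_params, movie.frame_period_s, traces.roi_ids
        )
        raster = build_raster(events, current.n_rois, movie.n_frames, movie.frame_period_s)
        dice = dice_matrix(raster, bin_width_frames)
        graph = build_graph(dice, current, raster, edge_threshold, session_label=f"{t_h}h")
        m = metrics(graph, raster)
        rows.append(
            {
                "session_time_h": t_h,
                "n_active": m.n_active,
                "n_edges": m.n_edges,
                "edges_per_active": m.edges_per_active,
            }
        )
        graphs.append(graph)

    table = pd.DataFrame(rows)
    prev = table["n_edges"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["pct_change_edges"] = 100.0 * (table["n_edges"] - prev) / prev
    return table, graphs
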