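"""Movie input/output and pixel-format conversion.

All analysis operates on ordered stacks of 8-bit grayscale frames. Movies are
read from multi-frame TIFF files or from directories of same-shaped
single-frame TIFF/PNG images (ordered lexicographically; zero-padded names
are the caller's responsibility). 24-bit RGB frames are reduced to 8-bit
grayscale on read, by default by extracting the green channel — the calcium
indicator (Fluo-4) emits in the green band — with an ITU-R BT.601 luma
option for bead-comparison workflows.

Conventions used throughout the package: pixel coordinates are (row, col),
0-based; frame indices 0-based; frame ``i`` is acquired at time
``i * frame_period_s`` (frame 0 at t = 0); intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .exceptions import EmptyInputError, FormatError, ParameterError, ShapeError

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class Movie:
    """An ordered stack of 8-bit grayscale frames with a frame period.

    Attributes
    ----------
    frames : numpy.ndarray
        Array of shape (n_frames, height, width), dtype uint8.
    frame_period_s : float
        Time between consecutive frames, seconds. Frame ``i`` is at time
        ``i * frame_period_s``.
    origin : str
        Source path, or ``"synthetic"`` for simulated movies.
    """

    frames: np.ndarray
    frame_period_s: float
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeError(
                f"movie frames must be (n_frames, height, width); got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise FormatError("movie pixel values must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if not (self.frame_period_s > 0):
            raise ParameterError(f"frame_period_s must be > 0; got {self.frame_period_s}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds."""
        return np.arange(self.n_frames) * self.frame_period_s


def rgb_to_gray8(image: np.ndarray, mode: str = "green") -> np.ndarray:
    """Reduce a 24-bit RGB frame to an 8-bit grayscale frame.

    Parameters
    ----------
    image : numpy.ndarray
        (H, W, 3) uint8 array. Already-gray (H, W) arrays pass through.
    mode : {"green", "luma"}
        "green" extracts the green channel (default; matches a green-emitting
        calcium indicator). "luma" computes round(0.299 R + 0.587 G + 0.114 B).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(
            f"expected an (H, W, 3) RGB frame or an (H, W) gray frame; got shape {image.shape}"
        )
    if mode == "green":
        return image[..., 1].astype(np.uint8)
    if mode == "luma":
        rgb = image.astype(np.float64)
        luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    raise ParameterError(f"unknown RGB reduction mode {mode!r}; valid modes: 'green', 'luma'")


def _read_frame(path: Path, rgb_mode: str) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return rgb_to_gray8(arr, mode=rgb_mode)


def read_movie(path: str | Path, frame_period_s: float, rgb_mode: str = "green") -> Movie:
    """Read a movie from a multi-frame TIFF or a directory of frames.

    Directory inputs are ordered lexicographically by file name; all frames
    must share one shape. RGB frames are reduced per :func:`rgb_to_gray8`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise EmptyInputError(f"no frame files (tif/tiff/png) found in directory {path}")
        frames = []
        shape: tuple[int, ...] | None = None
        for f in files:
            arr = _read_frame(f, rgb_mode)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ShapeError(
                    f"frame {f.name} has shape {arr.shape}, but earlier frames have {shape}"
                )
            frames.append(arr)
        stack = np.stack(frames)
    else:
        arr = tifffile.imread(path)
        if arr.size == 0:
            raise EmptyInputError(f"empty TIFF: {path}")
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4 and arr.shape[-1] in (3, 4):
            stack = np.stack([rgb_to_gray8(fr[..., :3], mode=rgb_mode) for fr in arr])
        elif arr.ndim == 3 and arr.shape[-1] == 3 and arr.shape[0] > 4:
            # single RGB frame (H, W, 3)
            stack = rgb_to_gray8(arr, mode=rgb_mode)[None]
        else:
            stack = arr
    return Movie(frames=stack, frame_period_s=frame_period_s, origin=str(path))


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as a multi-frame 8-bit grayscale TIFF (one page per frame)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    return path


def write_outputs(
    out_dir: str | Path,
    traces: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    graph: nx.Graph | None = None,
) -> dict[str, Path]:
    """Write analysis artifacts to ``out_dir`` in stable text formats.

    Traces and events go to CSV (``traces.csv``: one row per ROI x frame;
    ``events.csv``: one row per event). The connectivity graph goes to
    GraphML (``graph.graphml``) plus an edge-list CSV (``edges.csv`` with
    columns roi_i, roi_j, dice).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if traces is not None:
        p = out_dir / "traces.csv"
        traces.to_csv(p, index=False)
        written["traces"] = p
    if events is not None:
        p = out_dir / "events.csv"
        events.to_csv(p, index=False)
        written["events"] = p
    if graph is not None:
        p = out_dir / "graph.graphml"
        nx.write_graphml(graph, p)
        written["graph"] = p
        rows = [
            {"roi_i": min(int(u), int(v)), "roi_j": max(int(u), int(v)), "dice": d.get("dice", np.nan)}
            for u, v, d in graph.edges(data=True)
        ]
        edges = pd.DataFrame(rows, columns=["roi_i", "roi_j", "dice"]).sort_values(
            ["roi_i", "roi_j"], ignore_index=True
        )
        p = out_dir / "edges.csv"
        edges.to_csv(p, index=False)
        written["edges"] = p
    return written


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge-list CSV written by :func:`write_outputs`."""
    return pd.read_csv(path)
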