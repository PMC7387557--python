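"""End-to-end orchestration: simulate/read -> segment -> traces -> events ->
network -> reports, with a metadata record and deterministic outputs.

Re-running :func:`run` with the same configuration (including seed)
reproduces byte-identical CSV/GraphML artifacts; plots are best-effort
presentation artifacts and never load-bearing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, save_config
from .events import build_raster, death_analysis, detect_events
from .exceptions import CalfluorError
from .fluorometry import compute_traces
from .io import Movie, read_movie, write_movie, write_outputs
from .network import build_graph, dice_matrix, metrics
from .segment import segment_cells
from .simulate import preset, simulate, write_ground_truth

logger = logging.getLogger(__name__)

__all__ = ["run"]


def _acquire(config: RunConfig, out: Path):
    if config.preset is not None:
        params = preset(config.preset).replace(seed=config.seed, **config.sim_overrides)
        movie, truth = simulate(params)
        write_movie(movie, out / "movie.tif")
        write_ground_truth(truth, out)
        return movie, truth
    movie = read_movie(config.input_movie, config.frame_period_s, config.rgb_mode)
    return movie, None


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the run directory.

    Artifacts: movie.tif + ground truth (simulated inputs), rois.tif,
    traces.csv, events.csv, raster.csv, death.csv, graph.graphml,
    edges.csv, metrics.csv, config.toml, metadata.json, and (best-effort)
    plots/. Returns the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "acquire"
    try:
        movie, truth = _acquire(config, out)

        stage = "segment"
        rois = segment_cells(movie, config.segmentation)
        rois.write(out / "rois.tif")

        stage = "fluorometry"
        counts = {"n_frames": movie.n_frames, "n_rois": rois.n_rois}
        if rois.n_rois == 0:
            logger.warning("no ROIs found; writing empty outputs")
            write_outputs(out)
            _write_metadata(config, out, counts)
            return out
        traces = compute_traces(movie, rois, config.f_max_mode)

        stage = "detect"
        events = detect_events(
            traces.deriv, config.detection, movie.frame_period_s, traces.roi_ids
        )
        raster = build_raster(events, rois.n_rois, movie.n_frames, movie.frame_period_s)
        raster.to_dataframe().to_csv(out / "raster.csv")
        deaths, _ = death_analysis(
            events, movie.frame_period_s, config.death_hist_bin_s, movie.n_frames
        )
        deaths.to_csv(out / "death.csv", index=False)

        stage = "network"
        dice = dice_matrix(raster, config.bin_width_frames)
        graph = build_graph(dice, rois, raster, config.edge_threshold)
        m = metrics(graph, raster)
        counts.update(
            n_events=len(events),
            n_influx=int((events["kind"] == "influx").sum()),
            n_deaths=len(deaths),
            n_active=m.n_active,
            n_edges=m.n_edges,
        )

        stage = "write"
        write_outputs(out, traces=traces.to_dataframe(), events=events, graph=graph)
        with open(out / "metrics.csv", "w") as fh:
            fh.write("n_active,n_edges,edges_per_active\n")
            fh.write(f"{m.n_active},{m.n_edges},{m.edges_per_active:.6g}\n")
        _write_metadata(config, out, counts)

        if config.make_plots:
            stage = "plots"
            try:
                _plots(movie, traces, raster, graph, out / "plots")
            except Exception as exc:  # plots are never load-bearing
                logger.warning("plotting failed (non-fatal): %s", exc)
        return out
    except CalfluorError as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise


def _write_metadata(config: RunConfig, out: Path, counts: dict) -> None:
    save_config(config, out / "config.toml")
    meta = {
        "calfluor_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "input_movie": config.input_movie,
        "counts": counts,
        "config": {
            "edge_threshold": config.edge_threshold,
            "bin_width_frames": config.bin_width_frames,
            "detection": dataclasses.asdict(config.detection),
            "segmentation": dataclasses.asdict(config.segmentation),
            "sim_overrides": {
                k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
                for k, v in config.sim_overrides.items()
            },
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _plots(movie: Movie, traces, raster, graph, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 4))
    for i in range(min(traces.n_rois, 12)):
        ax.plot(traces.times_s, traces.f_star[i], lw=0.8)
    ax.set(xlabel="time (s)", ylabel="F* (background-normalized)")
    fig.savefig(plot_dir / "traces.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    rows, cols = np.nonzero(raster.raster)
    ax.scatter(cols * raster.frame_period_s, rows + 1, marker="|", s=40, color="k")
    ax.set(xlabel="time (s)", ylabel="ROI", title="influx raster")
    fig.savefig(plot_dir / "raster.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(movie.frames.max(axis=0), cmap="gray")
    for u, v in graph.edges():
        ax.plot(
            [graph.nodes[u]["x"], graph.nodes[v]["x"]],
            [graph.nodes[u]["y"], graph.nodes[v]["y"]],
            "c-",
            lw=1,
        )
    for _, d in graph.nodes(data=True):
        ax.plot(d["x"], d["y"], "r." if d["active"] else "b.", ms=6)
    ax.set_title("connectivity map")
    fig.savefig(plot_dir / "connectivity.png", dpi=110)
    plt.close(fig)
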