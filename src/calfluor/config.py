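"""Run configuration: one flat TOML file drives an end-to-end run.

The configuration gathers every tunable of the pipeline stages (simulation
preset and overrides, segmentation constants, detection thresholds, network
parameters, RGB reduction mode) plus seed and output directory. It
round-trips through TOML unchanged.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import ConfigurationError
from .events import DetectionParams
from .segment import SegmentationConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    Exactly one of ``input_movie`` (path) or ``preset`` (simulation regime
    name) must be set. ``sim_overrides`` are SimParams field overrides
    applied on top of the preset.
    """

    preset: str | None = "fast_session_150s"
    input_movie: str | None = None
    frame_period_s: float | None = None  # required for input_movie
    rgb_mode: str = "green"
    seed: int = 0
    out_dir: str = "calfluor_run"
    log_level: str = "INFO"
    sim_overrides: dict = field(default_factory=dict)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    edge_threshold: float = 0.5
    bin_width_frames: int = 1
    f_max_mode: str = "roi_mean"
    death_hist_bin_s: float = 3600.0
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.preset is None) == (self.input_movie is None):
            raise ConfigurationError("set exactly one of 'preset' or 'input_movie'")
        if self.input_movie is not None and not (
            self.frame_period_s and self.frame_period_s > 0
        ):
            raise ConfigurationError("input_movie requires a positive frame_period_s")
        if not (0 <= self.edge_threshold <= 1):
            raise ConfigurationError(
                f"edge_threshold must be in [0, 1]; got {self.edge_threshold}"
            )
        if self.bin_width_frames < 1:
            raise ConfigurationError("bin_width_frames must be >= 1")
        if self.rgb_mode not in ("green", "luma"):
            raise ConfigurationError("rgb_mode must be 'green' or 'luma'")
        if not (self.death_hist_bin_s > 0):
            raise ConfigurationError("death_hist_bin_s must be > 0")
        # nested dataclasses validate themselves on construction


def _to_tomlable(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return value


def _format_value(value) -> str:
    value = _to_tomlable(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig to TOML (flat [section] tables)."""
    lines: list[str] = []
    top = {
        k: getattr(config, k)
        for k in (
            "preset",
            "input_movie",
            "frame_period_s",
            "rgb_mode",
            "seed",
            "out_dir",
            "log_level",
            "edge_threshold",
            "bin_width_frames",
            "f_max_mode",
            "death_hist_bin_s",
            "make_plots",
        )
    }
    for k, v in top.items():
        if v is not None:
            lines.append(f"{k} = {_format_value(v)}")
    if config.sim_overrides:
        lines.append("\n[sim_overrides]")
        for k, v in config.sim_overrides.items():
            lines.append(f"{k} = {_format_value(v)}")
    lines.append("\n[segmentation]")
    for f_ in dataclasses.fields(config.segmentation):
        lines.append(f"{f_.name} = {_format_value(getattr(config.segmentation, f_.name))}")
    lines.append("\n[detection]")
    for f_ in dataclasses.fields(config.detection):
        lines.append(f"{f_.name} = {_format_value(getattr(config.detection, f_.name))}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file written by :func:`save_config`."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    seg = SegmentationConfig(**data.pop("segmentation", {}))
    det = DetectionParams(**data.pop("detection", {}))
    overrides = data.pop("sim_overrides", {})
    overrides = {k: (math.inf if v == "inf" else v) for k, v in overrides.items()}
    try:
        return RunConfig(segmentation=seg, detection=det, sim_overrides=overrides, **data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
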