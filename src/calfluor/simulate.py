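"""Synthetic calcium-fluorescence movie generator with ground truth.

Emulates the two acquisition regimes of a low-cost incubator microscope
recording Fluo-4-loaded cells:

* ``long_term_10h`` — 1 frame / 10 min for 10 h (61 frames including t = 0),
  used for slow calcium drift and single-spike cell-death timing;
* ``fast_session_150s`` — 1 Hz for 150 s, used for network-synchrony
  sessions.

The model: spatially separated round somata rendered as isotropic 2-D
Gaussian profiles (truncated at 3 sigma) on a uniform background; each cell
carries a resting brightness plus calcium transients (linear rise over
``rise_frames``, exponential decay with ``decay_tau_s``) driven by a spike
train that mixes independent Poisson events with shared network events
joined with probability ``p_sync``; global multiplicative photobleaching;
Poisson shot noise followed by additive Gaussian read noise; clipping to
[0, 255] and 8-bit quantization.

Dying cells receive a single large influx (``death_amplitude_factor`` x the
ordinary transient) that stays elevated until a terminal efflux ``dT``
frames later, after which the cell's own signal falls permanently to
``death_residual_fraction`` of its resting value — a one-spike
influx-then-efflux signature whose delay dT the downstream death analysis
recovers.

Same ``SimParams`` (including seed) always produce byte-identical movies.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import ParameterError, PlacementError
from .io import Movie

__all__ = [
    "SimParams",
    "GroundTruth",
    "preset",
    "generate_spike_trains",
    "render_movie",
    "simulate",
    "write_ground_truth",
    "read_ground_truth",
]

_PRESETS = ("long_term_10h", "fast_session_150s")

# independent sub-streams of the master seed (SeedSequence spawn keys)
_KEY_TRAINS, _KEY_PLACE, _KEY_DEATH, _KEY_NOISE = 0, 1, 2, 3


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic movie generator.

    Defaults describe the fast 1-Hz session regime; use :func:`preset` for
    the documented regime presets. Intensities are in 8-bit digital numbers
    (DN); the shot-noise model treats DN as photoelectron counts, so at
    ``baseline_level=100`` the background is shot-limited at roughly the
    17 dB patch signal-to-noise level of a consumer CMOS microscope.
    """

    field_height_px: int = 256
    field_width_px: int = 256
    n_cells: int = 30
    cell_radius_px: float = 3.0  # Gaussian-profile sigma
    min_center_distance_px: float = 20.0
    frame_period_s: float = 1.0
    n_frames: int = 150
    baseline_level: float = 100.0
    cell_baseline: float = 80.0  # resting cell brightness above background
    cell_amplitude: float = 80.0
    rise_frames: int = 0
    decay_tau_s: float = 3.0
    bleach_tau_s: float = math.inf
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    rate_independent_hz: float = 0.01
    rate_network_hz: float = 0.04
    p_sync: float = 0.6
    jitter_frames: int = 0
    death_fraction: float = 0.0
    death_amplitude_factor: float = 3.0
    death_residual_fraction: float = 0.05
    death_dt_frames_distribution: tuple[tuple[int, float], ...] = (
        (6, 0.3),
        (12, 0.4),
        (18, 0.3),
    )
    seed: int = 0
    # When imaging one field over repeated sessions, fix placement_seed across
    # the sessions (cells stay put) while seed varies the activity and noise.
    placement_seed: int | None = None

    def __post_init__(self) -> None:
        if self.field_height_px < 1 or self.field_width_px < 1:
            raise ParameterError("field dimensions must be positive")
        if self.n_cells < 0 or self.n_frames < 1:
            raise ParameterError("n_cells must be >= 0 and n_frames >= 1")
        if not (self.cell_radius_px > 0 and self.min_center_distance_px > 0):
            raise ParameterError("cell_radius_px and min_center_distance_px must be positive")
        if not (self.frame_period_s > 0 and self.decay_tau_s > 0 and self.bleach_tau_s > 0):
            raise ParameterError("frame_period_s, decay_tau_s, bleach_tau_s must be positive")
        if not (0 <= self.baseline_level <= 255):
            raise ParameterError("baseline_level must be in [0, 255]")
        if self.cell_amplitude <= 0 or self.cell_baseline < 0:
            raise ParameterError("cell_amplitude must be > 0 and cell_baseline >= 0")
        if self.rise_frames < 0 or self.read_noise_sd < 0:
            raise ParameterError("rise_frames and read_noise_sd must be >= 0")
        for name in ("rate_independent_hz", "rate_network_hz"):
            rate = getattr(self, name)
            if not np.isfinite(rate) or rate < 0:
                raise ParameterError(f"{name} must be finite and >= 0; got {rate}")
        if not (0 <= self.p_sync <= 1) or not (0 <= self.death_fraction <= 1):
            raise ParameterError("p_sync and death_fraction must be in [0, 1]")
        if self.jitter_frames < 0:
            raise ParameterError("jitter_frames must be >= 0")
        dist = self.death_dt_frames_distribution
        if dist:
            total = sum(p for _, p in dist)
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"death_dt_frames_distribution probabilities sum to {total}, not 1"
                )
            if any(dt < 1 for dt, _ in dist):
                raise ParameterError("death dT values must be >= 1 frame")

    def replace(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Ground-truth annotations of a rendered synthetic movie.

    ``spike_times`` lists influx-onset frames of ordinary calcium transients
    per cell (cell order matches ``cell_centers``); death transients are
    recorded separately in ``death_events`` as (influx_frame, efflux_frame)
    or None for surviving cells. ``cell_masks`` labels each cell's 3-sigma
    footprint with value cell_index + 1.
    """

    cell_centers: list[tuple[int, int]]
    cell_masks: np.ndarray
    spike_times: list[list[int]]
    death_events: list[tuple[int, int] | None]
    params_echo: SimParams

    def __post_init__(self) -> None:
        n = self.params_echo.n_frames
        for train in self.spike_times:
            if any(not (0 <= t < n) for t in train):
                raise ParameterError("spike frame index outside [0, n_frames)")
        for ev in self.death_events:
            if ev is not None and ev[1] <= ev[0]:
                raise ParameterError("death efflux_frame must exceed influx_frame")


def preset(name: str) -> SimParams:
    """Return the SimParams of a documented acquisition regime.

    ``"long_term_10h"``: 1 frame / 10 min for 10 h (61 frames including
    t = 0), 50 HEK-like cells, no network coupling, slow bleaching, 40% of
    cells dying. ``"fast_session_150s"``: 1 Hz for 150 s, 30 neuron-like
    cells with shared network events (p_sync = 0.6), no deaths.
    """
    if name == "long_term_10h":
        return SimParams(
            frame_period_s=600.0,
            n_frames=61,
            n_cells=50,
            cell_baseline=120.0,  # HEK-like bright resting somata
            cell_amplitude=45.0,
            rate_independent_hz=2.8e-5,  # ~1 ordinary transient per cell per 10 h
            rate_network_hz=0.0,
            p_sync=0.0,
            decay_tau_s=1200.0,
            bleach_tau_s=36000.0,
            death_fraction=0.4,
        )
    if name == "fast_session_150s":
        return SimParams(
            frame_period_s=1.0,
            n_frames=150,
            n_cells=30,
            rate_independent_hz=0.01,
            rate_network_hz=0.04,
            p_sync=0.6,
            decay_tau_s=3.0,
            bleach_tau_s=math.inf,
            death_fraction=0.0,
        )
    raise ParameterError(f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}")


def _rng(params: SimParams, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(key,)))


def generate_spike_trains(params: SimParams) -> list[list[int]]:
    """Draw per-cell influx-onset frames (sorted, duplicates collapsed).

    Each cell's train is the union of its own homogeneous-rate events
    (``rate_independent_hz``) and the shared network events
    (``rate_network_hz``) it joins with probability ``p_sync``. Events are
    Bernoulli per frame with probability rate x frame period (clipped to 1).
    Network events are frame-aligned unless ``jitter_frames`` > 0, in which
    case each participant is shifted by a uniform integer in
    [-jitter_frames, +jitter_frames] (clipped to the recording).
    """
    rng = _rng(params, _KEY_TRAINS)
    dt = params.frame_period_s
    n, t = params.n_cells, params.n_frames
    p_ind = min(params.rate_independent_hz * dt, 1.0)
    p_net = min(params.rate_network_hz * dt, 1.0)

    independent = rng.random((n, t)) < p_ind
    network_frames = np.flatnonzero(rng.random(t) < p_net)
    joins = rng.random((n, network_frames.size)) < params.p_sync

    trains: list[list[int]] = []
    for c in range(n):
        frames = set(np.flatnonzero(independent[c]).tolist())
        joined = network_frames[joins[c]]
        if params.jitter_frames > 0 and joined.size:
            shift = rng.integers(-params.jitter_frames, params.jitter_frames + 1, joined.size)
            joined = np.clip(joined + shift, 0, t - 1)
        frames.update(int(f) for f in joined)
        trains.append(sorted(frames))
    return trains


def _place_centers(params: SimParams) -> list[tuple[int, int]]:
    """Dart-throwing placement with a 3-sigma border margin."""
    entropy = params.seed if params.placement_seed is None else params.placement_seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(_KEY_PLACE,)))
    margin = int(math.ceil(3 * params.cell_radius_px)) + 1
    h, w = params.field_height_px, params.field_width_px
    if params.n_cells and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise PlacementError("field too small for the cell radius margin")
    centers: list[tuple[int, int]] = []
    min_d2 = params.min_center_distance_px**2
    max_tries = 1000 * max(params.n_cells, 1)
    tries = 0
    while len(centers) < params.n_cells:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {params.n_cells} cells with "
                f"min_center_distance_px={params.min_center_distance_px} in a "
                f"{h}x{w} field after {max_tries} tries"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def _transient_kernel(params: SimParams) -> np.ndarray:
    """Unit-peak kernel: linear rise over rise_frames, then exp decay.

    k[rise_frames] = 1 is the unique maximum (rise samples are
    (j+1)/(rise_frames+1); decay samples exp(-j dt / tau) for j >= 1).
    """
    dt, tau, rise = params.frame_period_s, params.decay_tau_s, params.rise_frames
    n_decay = min(params.n_frames, int(math.ceil(8 * tau / dt)) + 1)
    rise_part = (np.arange(1, rise + 2)) / (rise + 1)
    decay_part = np.exp(-np.arange(1, n_decay) * dt / tau)
    return np.concatenate([rise_part, decay_part])[: params.n_frames]


def _draw_death_events(params: SimParams) -> list[tuple[int, int] | None]:
    """Pick dying cells and their (influx, efflux) frames."""
    rng = _rng(params, _KEY_DEATH)
    n, t = params.n_cells, params.n_frames
    n_die = int(round(params.death_fraction * n))
    events: list[tuple[int, int] | None] = [None] * n
    if n_die == 0:
        return events
    dts = np.array([dt for dt, _ in params.death_dt_frames_distribution], dtype=int)
    probs = np.array([p for _, p in params.death_dt_frames_distribution], dtype=float)
    if dts.size == 0:
        raise ParameterError("death_fraction > 0 requires a death_dt_frames_distribution")
    which = rng.choice(n, size=n_die, replace=False)
    for c in which:
        d_t = int(rng.choice(dts, p=probs / probs.sum()))
        last_influx = t - d_t - 2  # leave one post-efflux frame
        if last_influx < 1:
            raise ParameterError(
                f"death dT of {d_t} frames does not fit in a {t}-frame recording"
            )
        influx = int(rng.integers(1, last_influx + 1))
        events[c] = (influx, influx + d_t)
    return events


def render_movie(
    params: SimParams, trains: list[list[int]] | None = None
) -> tuple[Movie, GroundTruth]:
    """Render a synthetic movie (with noise and quantization) plus ground truth.

    If ``trains`` is None they are generated from ``params`` (same seed,
    same result as :func:`generate_spike_trains`). Dying cells have their
    ordinary train suppressed so their trace carries exactly one influx and
    one terminal efflux.
    """
    if trains is None:
        trains = generate_spike_trains(params)
    if len(trains) != params.n_cells:
        raise ParameterError(
            f"{len(trains)} trains supplied for {params.n_cells} cells"
        )
    h, w, t = params.field_height_px, params.field_width_px, params.n_frames
    centers = _place_centers(params)
    death_events = _draw_death_events(params)

    sigma = params.cell_radius_px
    radius = int(math.ceil(3 * sigma))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    dist2 = yy**2 + xx**2
    footprint = np.exp(-dist2 / (2 * sigma**2))
    footprint[dist2 > (3 * sigma) ** 2] = 0.0  # truncate at 3 sigma

    masks = np.zeros((h, w), dtype=np.uint16)
    clean = np.full((t, h, w), params.baseline_level, dtype=np.float64)
    kernel = _transient_kernel(params)
    spike_times: list[list[int]] = []

    for c, (r0, c0) in enumerate(centers):
        death = death_events[c]
        train = [] if death is not None else list(trains[c])
        spike_times.append(train)

        sig = np.zeros(t)
        indicator = np.zeros(t)
        for f in train:
            indicator[f] += 1.0
        sig += params.cell_amplitude * np.convolve(indicator, kernel)[:t]
        if death is not None:
            influx, efflux = death
            amp = params.death_amplitude_factor * params.cell_amplitude
            # rise to the plateau, hold until the terminal efflux
            rise = kernel[: params.rise_frames + 1]
            stop = min(influx + rise.size, efflux + 1)
            sig[influx:stop] += amp * rise[: stop - influx]
            sig[stop : efflux + 1] += amp
        sig += params.cell_baseline
        if death is not None:
            sig[death[1] + 1 :] = params.death_residual_fraction * params.cell_baseline

        rows = slice(r0 - radius, r0 + radius + 1)
        cols = slice(c0 - radius, c0 + radius + 1)
        masks[rows, cols][footprint > 0] = c + 1
        clean[:, rows, cols] += sig[:, None, None] * footprint[None, :, :]

    if np.isfinite(params.bleach_tau_s):
        times = np.arange(t) * params.frame_period_s
        clean *= np.exp(-times / params.bleach_tau_s)[:, None, None]

    noise_rng = _rng(params, _KEY_NOISE)
    noisy = clean
    if params.shot_noise:
        noisy = noise_rng.poisson(np.clip(noisy, 0, None)).astype(np.float64)
    if params.read_noise_sd > 0:
        noisy = noisy + noise_rng.normal(0.0, params.read_noise_sd, size=noisy.shape)
    frames = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    movie = Movie(frames=frames, frame_period_s=params.frame_period_s, origin="synthetic")
    truth = GroundTruth(
        cell_centers=centers,
        cell_masks=masks,
        spike_times=spike_times,
        death_events=death_events,
        params_echo=params,
    )
    return movie, truth


def simulate(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Generate trains and render the movie in one call."""
    return render_movie(params, generate_spike_trains(params))


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write ground truth as a JSON sidecar plus a labeled-mask TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_path = out_dir / "ground_truth_masks.tif"
    tifffile.imwrite(mask_path, truth.cell_masks)
    payload = {
        "cell_centers": [list(c) for c in truth.cell_centers],
        "spike_times": truth.spike_times,
        "death_events": [list(ev) if ev is not None else None for ev in truth.death_events],
        "params": {
            k: (v if not isinstance(v, tuple) else [list(x) for x in v])
            for k, v in dataclasses.asdict(truth.params_echo).items()
            if not (isinstance(v, float) and math.isinf(v))
        },
        "masks_file": mask_path.name,
    }
    json_path = out_dir / "ground_truth.json"
    json_path.write_text(json.dumps(payload, indent=1))
    return {"json": json_path, "masks": mask_path}


def read_ground_truth(out_dir: str | Path) -> dict:
    """Read the JSON sidecar written by :func:`write_ground_truth`."""
    out_dir = Path(out_dir)
    payload = json.loads((out_dir / "ground_truth.json").read_text())
    payload["cell_masks"] = tifffile.imread(out_dir / payload["masks_file"])
    return payload
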