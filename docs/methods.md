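# Methods

This note records the models, conventions, parameter defaults and known
limitations of `calfluor`. Everything quantitative claimed here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Conventions

Pixel coordinates are (row, col), 0-based. Frame indices are 0-based; frame
`i` is acquired at `i × frame_period_s`, so an N-frame recording spans
`(N−1) × frame_period_s` of wall time and the 10-h regime at one frame per
10 min has 61 frames including the frame at t = 0. Intervals are half-open.
All analysis operates on 8-bit grayscale; 24-bit RGB frames are reduced on
read, by default by taking the green channel (a green-emitting calcium
indicator with ~480 nm excitation and a 510–610 nm emission band puts
essentially all signal there), with BT.601 luma as the alternative for
broadband bead images.

## Trace model

For each ROI, `F̄(t)` is the plain mean of its pixels per frame, and
`F_Bkg(t)` the mean over the background mask (the complement of all ROIs
dilated by 5 px). The background is per-frame rather than static: over 10 h
the illumination and bleaching state drift, and a time-varying background
makes `F* = F̄ / F_Bkg` insensitive to any multiplicative envelope shared
by cells and background (verified on synthetic movies: bleached and
unbleached renderings agree in `F*` to within 8-bit quantization).

`F_max` in `F_rel = (F̄ − F_Bkg)/F_max` is the global maximum of the
ROI-mean traces, not the raw pixel maximum: `F_rel` divides an ROI-level
quantity and a single hot pixel should not rescale every trace. A raw-pixel
variant is available via `f_max_mode`.

The derivative is the backward difference `(F*(t) − F*(t−1))/Δt`, defined
for t ≥ 1 and stored in 1/s; an event detected at derivative index t
carries frame t's timestamp (causal, stable under noise).

## Double-threshold event detection

Per ROI, the positive threshold is `θ⁺ = max(static, k·s)` with static =
0.05, k = 5, and `s` a spread estimate of the derivative series; the
negative threshold is `θ⁻ = −θ⁺` ("strict" reading, parallel construction
with the positive side; a "lenient" `−min(static, k·s)` switch exists).
Runs of consecutive supra-threshold frames merge into one event timed at
the extreme derivative — at 1 Hz a single indicator transient's rise can
span two frames, and merging keeps one event per transient.

Units: the static cutoff is interpreted per frame (dimensionless ΔF* per
frame) and the derivative is rescaled by Δt before comparison. The same
0.05 then applies coherently to both the 1-s and the 600-s frame period; a
`threshold_units = "second"` switch treats it as 1/s instead.

Spread estimate: the default is the scaled median absolute deviation
(1.4826 × MAD), which estimates the noise floor of the derivative and is
insensitive to the transients themselves. The plain whole-trace standard
deviation (population, ddof = 0) is available with `robust=False`, but it
self-masks: the events contribute to the SD they are tested against, and
on a 61-frame long-term trace the two large death transients alone push
5 × SD above the influx amplitude, so a trace's own spikes can raise the
threshold past themselves. The robust default keeps the varying threshold
a noise estimate, which is what a double threshold needs; with an
essentially clean derivative the MAD is ~0 and the static 0.05 governs,
reproducing the same decisions as the SD variant on sparse traces.

## Cell-death (ΔT) analysis

ROIs with exactly one influx and exactly one efflux, influx first, are
selected as candidate dying cells; ΔT is the frame gap times the frame
period. Histograms of influx time, efflux time and ΔT use a 1-h bin by
default, matching the 10-h regime. No apoptosis/necrosis classification is
attempted; ΔT is reported as a timing observable only.

## Synchrony and connectivity

Influx rasters are optionally binned (bin occupied iff it contains an
influx; default bin width 1 frame, i.e. frame-exact coincidence — a ±1
frame tolerance is available as bin width 3). Dice(a,b) = 2|a∩b|/(|a|+|b|)
on occupied-bin sets; silent-silent pairs are undefined and stored as 0
with a flag. The implementation is vectorized and is checked exactly
against a brute-force set-intersection oracle.

Edges require both ROIs active (≥ 1 influx in the session) and Dice ≥
θ_edge. θ_edge defaults to 0.5 — the midpoint of the Dice range; it is
deliberately prominent in config and CLI because every edge count depends
on it. Vertices sit at ROI centroids, so the GraphML renders directly over
the field of view. Across sessions, ROIs are segmented once on the first
session and reused so vertices stay comparable; per-session re-segmentation
is a flag.

## Segmentation

Maximum-intensity projection over time → Gaussian smoothing (σ 2 px) →
global Otsu threshold → 8-connected components → area filter (30–2000 px)
→ consecutive relabeling; centroids are projection-intensity-weighted. The
method is the simplest adequate one for bright, well-separated somata on a
dark background and every constant is in `SegmentationConfig`; no watershed
splitting of touching cells is attempted in v1 (separation is assumed, and
enforced in the generator by a minimum center distance). A constant
projection yields zero ROIs with a warning, not an error. Manually drawn
masks enter through `manual_rois` unchanged.

## Synthetic movie generator

The generator emulates what the analysis assumes, with ground truth for
every stage:

- **Geometry**: isotropic 2-D Gaussian somata (σ = 3 px) truncated at 3σ,
  centers ≥ 20 px apart by dart throwing, on a 256 × 256 field.
- **Activity**: per-cell independent Bernoulli-per-frame events plus shared
  network events joined with probability `p_sync` (frame-aligned by
  default; optional ±1-frame jitter). The transient kernel rises linearly
  over `rise_frames` (default 0 — an indicator with sub-second rise
  sampled at ≤ 1 Hz rises within one frame) and decays as
  `exp(−t/decay_tau_s)` (3 s fast regime, 1200 s long-term).
- **Death**: a dying cell's ordinary train is suppressed; it receives one
  large influx (3 × the ordinary amplitude) that *plateaus* until a
  terminal efflux ΔT frames later, after which the cell's own signal drops
  permanently to 5 % of its resting level. The plateau (rather than a
  decaying transient) reflects sustained calcium entry before membrane
  failure and gives the one-influx-one-efflux signature the ΔT analysis
  selects; a decaying death transient would register its own decay as a
  second efflux and the cell would (correctly) be rejected by the
  exactly-one-of-each rule. ΔT is drawn from a discrete distribution
  (default 1 h/2 h/3 h at 0.3/0.4/0.3 for the long-term preset).
- **Noise**: Poisson shot noise with mean equal to the noiseless intensity
  (treating 8-bit counts as photoelectrons), then Gaussian read noise
  (σ = 2), then clipping and 8-bit quantization — a standard CMOS model.
  At the default background level of 100 counts this measures ≈ 17 dB
  median patch SNR, the regime of a consumer digital microscope; the noise
  statistics of any specific camera are not modeled.
- **Brightness defaults**: background 100; fast preset cells rest 80 above
  background with 80-count transients; long-term preset cells rest 120
  above background with 45-count transients (bright HEK-like somata with
  modest slow transients). Resting brightness is deliberately high enough
  that silent cells segment reliably; a cell that never fires still
  carries indicator.
- **Determinism**: all randomness derives from independent child streams
  of one seed; identical parameters give byte-identical movies. A separate
  `placement_seed` lets repeated sessions share cell geometry while
  activity and noise vary — how one culture imaged every 2 h behaves.

What the generator does **not** emulate: optical PSF and resolution
limits, motion, focus drift, neuropil contamination, touching/overlapping
cells, inhomogeneous illumination, or any specific camera's gain and
fixed-pattern noise. Recovery results on synthetic data (detection F1,
death-ΔT recovery, segmentation precision/recall) therefore demonstrate
the correctness and calibration of the pipeline under its own assumptions,
not performance on arbitrary real recordings.

## Image-quality protocol

SNR/PSNR/MAE/RMSE use the conventional image-comparison definitions
(`snr = 10·log10(Σr²/Σ(r−t)²)`, `psnr = 20·log10(255/rmse)`); the
paired-patch reading is implemented, not a background-region noise
estimate. Identical patches give +∞ dB, preserved in reports (capping is a
presentation concern). MAE ≤ RMSE always (Jensen); all metrics except SNR
are symmetric under pair swap — SNR is reference-normalized, and the
asymmetry is intentional. The per-microscope dB values of any physical
system depend on its optics and samples and are out of scope; on synthetic
data the measured RMSE converges to a known injected noise σ.

## Problem sizes and numerical choices

The test suite and acceptance script run on 256 × 256 fields with 30–50
cells, 10 seeds for stochastic checks and 3 seeds for the slower long-term
checks — sizes chosen to exercise every code path at full preset scale
while a complete verification pass stays within a few minutes on one CPU.
Ties in run-extremum timing break toward the earlier frame; spread
estimates use the population SD (ddof 0); backgrounds must be strictly
positive for normalization (a zero background raises with the frame
index); empty selections return empty tables, never errors.

## Known limitations

- Otsu segmentation assumes a bimodal projection; dense cultures or
  strong vignetting will need the manual-ROI path.
- The robust varying threshold assumes most derivative samples are
  event-free; a cell firing on most frames would need the plain-SD variant
  or a longer recording.
- Dice on binary bins ignores rate information: two cells firing at very
  different rates can still show moderate Dice by chance; no surrogate
  null is implemented in v1.
- `F_rel` shares one `F_max` across ROIs by design, so it is comparable
  across cells but not bounded per cell.
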