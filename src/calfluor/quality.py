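"""Patch-based image-quality comparison (SNR, PSNR, MAE, RMSE).

Protocol: fixed-size square patches (default 43 x 43 px) are extracted
around bright objects (fluorescent beads or cell bodies) and compared
pairwise — every unordered pair within one image ("within" mode), or a
seeded random pairing of patches across images ("randomized_inter" mode).

Definitions, with patches treated as real arrays r (reference) and t (test):

    mae  = mean(|r - t|)
    rmse = sqrt(mean((r - t)^2))
    psnr = 20 log10(255 / rmse)           [dB, 8-bit peak]
    snr  = 10 log10(sum r^2 / sum (r-t)^2) [dB, reference-normalized]

Identical patches give +inf dB (preserved, reported as "inf" in CSV). All
four metrics are symmetric under swapping the pair except snr, which is
normalized by the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import BoundaryError, CardinalityError, ParameterError, ShapeError

DEFAULT_PATCH_SIZE = 43
PEAK = 255.0

__all__ = [
    "extract_patches",
    "mae",
    "rmse",
    "psnr",
    "snr",
    "compare_patch_set",
    "intensity_histogram",
    "QualityReport",
]


def extract_patches(
    image: np.ndarray,
    centers: list[tuple[float, float]],
    size: int = DEFAULT_PATCH_SIZE,
) -> list[np.ndarray]:
    """Extract axis-aligned square patches centered on the given (row, col) points.

    Centers are rounded to the nearest pixel and must be at least
    ceil(size/2) from every border.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D image; got shape {image.shape}")
    if size < 1:
        raise ParameterError("patch size must be >= 1")
    half = size // 2
    h, w = image.shape
    patches = []
    for center in centers:
        r = int(round(center[0]))
        c = int(round(center[1]))
        r0, c0 = r - half, c - half
        if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
            raise BoundaryError(
                f"center {center} too close to the border of a {h}x{w} image "
                f"for a {size}x{size} patch"
            )
        patches.append(image[r0 : r0 + size, c0 : c0 + size].copy())
    return patches


def _as_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(reference, dtype=np.float64)
    t = np.asarray(test, dtype=np.float64)
    if r.shape != t.shape:
        raise ShapeError(f"patch shapes differ: {r.shape} vs {t.shape}")
    return r, t


def mae(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean absolute error, pixels as reals."""
    r, t = _as_pair(reference, test)
    return float(np.mean(np.abs(r - t)))


def rmse(reference: np.ndarray, test: np.ndarray) -> float:
    """Root-mean-square error, pixels as reals."""
    r, t = _as_pair(reference, test)
    return float(np.sqrt(np.mean((r - t) ** 2)))


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio, dB, with an 8-bit peak of 255."""
    e = rmse(reference, test)
    if e == 0:
        return float("inf")
    return float(20.0 * np.log10(PEAK / e))


def snr(reference: np.ndarray, test: np.ndarray) -> float:
    """Signal-to-noise ratio, dB: reference power over difference power."""
    r, t = _as_pair(reference, test)
    noise = float(np.sum((r - t) ** 2))
    if noise == 0:
        return float("inf")
    signal = float(np.sum(r**2))
    with np.errstate(divide="ignore"):  # all-zero reference -> -inf dB
        return float(10.0 * np.log10(signal / noise))


@dataclass
class QualityReport:
    """Per-pair metric records plus boxplot-ready summary statistics."""

    pairs: pd.DataFrame  # columns: ref_image, ref_idx, test_image, test_idx, snr_db, psnr_db, mae, rmse
    mode: str

    def summary(self) -> pd.DataFrame:
        """Mean, SD and quartiles per metric over all pairs."""
        metrics = self.pairs[["snr_db", "psnr_db", "mae", "rmse"]]
        return metrics.describe().loc[["mean", "std", "25%", "50%", "75%"]]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(path, index=False)  # pandas writes inf as "inf"
        return path


def _record(ref_key, ref_idx, test_key, test_idx, r, t) -> dict:
    return {
        "ref_image": ref_key,
        "ref_idx": ref_idx,
        "test_image": test_key,
        "test_idx": test_idx,
        "snr_db": snr(r, t),
        "psnr_db": psnr(r, t),
        "mae": mae(r, t),
        "rmse": rmse(r, t),
    }


def compare_patch_set(
    patches_by_image: dict[str, list[np.ndarray]],
    mode: str = "within",
    seed: int = 0,
) -> QualityReport:
    """Compare patches pairwise, within images or randomized across images.

    "within": every unordered pair of patches of the same image. Requires
    >= 2 patches in each image.

    "randomized_inter": patches of each image are shuffled with the given
    seed and paired positionally across consecutive image pairs (image k as
    reference vs image k+1 as test); the number of pairs is the minimum
    group size. Requires >= 2 images with >= 1 patch each.
    """
    rows: list[dict] = []
    if mode == "within":
        for key, patches in patches_by_image.items():
            if len(patches) < 2:
                raise CardinalityError(
                    f"within-image comparison needs >= 2 patches; image {key!r} has {len(patches)}"
                )
            for i in range(len(patches)):
                for j in range(i + 1, len(patches)):
                    rows.append(_record(key, i, key, j, patches[i], patches[j]))
    elif mode == "randomized_inter":
        keys = list(patches_by_image)
        if len(keys) < 2:
            raise CardinalityError("inter-image comparison needs >= 2 images")
        if any(len(patches_by_image[k]) < 1 for k in keys):
            raise CardinalityError("every image needs >= 1 patch for inter comparison")
        rng = np.random.default_rng(seed)
        n_pairs = min(len(patches_by_image[k]) for k in keys)
        order = {k: rng.permutation(len(patches_by_image[k])) for k in keys}
        for a, b in zip(keys[:-1], keys[1:]):
            for idx in range(n_pairs):
                i, j = int(order[a][idx]), int(order[b][idx])
                rows.append(_record(a, i, b, j, patches_by_image[a][i], patches_by_image[b][j]))
    else:
        raise ParameterError(
            f"unknown mode {mode!r}; valid modes: 'within', 'randomized_inter'"
        )
    columns = ["ref_image", "ref_idx", "test_image", "test_idx", "snr_db", "psnr_db", "mae", "rmse"]
    return QualityReport(pairs=pd.DataFrame(rows, columns=columns), mode=mode)


def intensity_histogram(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Histogram of an 8-bit image; with n_bins=256 bin i covers value i."""
    image = np.asarray(image)
    counts, _ = np.histogram(image, bins=n_bins, range=(0, 256))
    return counts
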