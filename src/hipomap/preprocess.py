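"""Tissue detection, grid patch extraction and naive reference color
normalization for plain RGB slide images.

Stained tissue absorbs light, so tissue pixels are darker than the bright
scanner background; tissue is detected by thresholding a Gaussian-blurred
grayscale of the image (Otsu's method by default).  Patches are cut on a
non-overlapping grid from the top-left origin with half-open pixel intervals,
trailing partial tiles discarded, and kept only when at least a minimum
fraction of their footprint is tissue (default 20%).  Color normalization is
the naive Reinhard-style per-channel mean/sd transfer towards a reference
image, in RGB by default (LAB optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2gray, rgb2lab
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "TissueMask",
    "ReferenceStats",
    "detect_tissue",
    "extract_patches",
    "reference_stats",
    "color_normalize",
    "DEFAULT_MIN_TISSUE_FRAC",
]

#: minimum tissue fraction for a patch to be kept
DEFAULT_MIN_TISSUE_FRAC = 0.2

#: fallback grayscale threshold when the image has no contrast for Otsu
_FLAT_IMAGE_THRESHOLD = 0.8


@dataclass
class TissueMask:
    mask: np.ndarray  # (H, W) bool, True = tissue
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.mask.shape != tuple(self.source_shape):
            raise ValueError("mask shape does not match source shape")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class ReferenceStats:
    """Per-channel mean/sd of a reference image in ``colorspace``."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray    # (3,)
    colorspace: str = "rgb"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("reference channel standard deviations must be > 0")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return image


def detect_tissue(image: np.ndarray, blur_sigma: float = 2.0,
                  threshold: float | str = "auto") -> TissueMask:
    """Blur, threshold, and return the darker-than-threshold tissue mask.

    ``threshold='auto'`` uses Otsu on the blurred grayscale; a contrast-free
    image falls back to a fixed threshold of 0.8 so blank (all-bright) inputs
    yield an empty mask.
    """
    image = _check_rgb(image)
    gray = rgb2gray(image)
    blurred = gaussian(gray, sigma=blur_sigma) if blur_sigma > 0 else gray
    if threshold == "auto":
        if np.ptp(blurred) < 1e-12:
            thr = _FLAT_IMAGE_THRESHOLD
        else:
            thr = float(threshold_otsu(blurred))
    else:
        thr = float(threshold)
    return TissueMask(mask=blurred < thr, source_shape=gray.shape)


def extract_patches(image: np.ndarray, mask: TissueMask, patch_size: int,
                    min_tissue_frac: float = DEFAULT_MIN_TISSUE_FRAC):
    """Tile the image into non-overlapping ``patch_size`` squares and keep
    those with tissue fraction >= ``min_tissue_frac``.

    Returns a list of ``(patch, grid_row, grid_col)``; tiles are half-open
    pixel intervals from the top-left origin, trailing partial tiles dropped.
    A patch size larger than the image yields an empty list.
    """
    image = _check_rgb(image)
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    if not 0.0 <= min_tissue_frac <= 1.0:
        raise ValueError("min_tissue_frac must be in [0, 1]")
    if mask.source_shape != image.shape[:2]:
        raise ValueError("tissue mask does not match image shape")
    h, w = image.shape[:2]
    out = []
    for gr in range(h // patch_size):
        for gc in range(w // patch_size):
            r0, c0 = gr * patch_size, gc * patch_size
            frac = mask.mask[r0:r0 + patch_size, c0:c0 + patch_size].mean()
            if frac >= min_tissue_frac:
                out.append((image[r0:r0 + patch_size, c0:c0 + patch_size], gr, gc))
    return out


def _to_space(image: np.ndarray, colorspace: str) -> np.ndarray:
    if colorspace == "rgb":
        return image
    if colorspace == "lab":
        return rgb2lab(image)
    raise ValueError(f"unknown colorspace {colorspace!r}; use 'rgb' or 'lab'")


def reference_stats(image: np.ndarray, colorspace: str = "rgb") -> ReferenceStats:
    """Channel mean/sd of a (high-quality) reference image."""
    image = _check_rgb(image)
    arr = _to_space(image, colorspace).reshape(-1, 3)
    sd = arr.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("reference image has a zero-variance channel")
    return ReferenceStats(mean=arr.mean(axis=0), sd=sd, colorspace=colorspace)


def color_normalize(image: np.ndarray, ref: ReferenceStats) -> np.ndarray:
    """Per-channel standardize-and-rescale towards the reference statistics.

    A zero-variance input channel is passed through shifted to the reference
    mean.  Output is clipped to [0, 1].
    """
    image = _check_rgb(image)
    arr = _to_space(image, ref.colorspace)
    mean = arr.reshape(-1, 3).mean(axis=0)
    sd = arr.reshape(-1, 3).std(axis=0)
    out = np.empty_like(arr)
    for ch in range(3):
        if sd[ch] <= 0:
            out[..., ch] = arr[..., ch] - mean[ch] + ref.mean[ch]
        else:
            out[..., ch] = (arr[..., ch] - mean[ch]) / sd[ch] * ref.sd[ch] \
                + ref.mean[ch]
    if ref.colorspace == "lab":
        out = lab2rgb(out)
    return np.clip(out, 0.0, 1.0)
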