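"""Tissue-region extraction from slide images.

The tissue slice sits dark on a bright slide background.  The region is found
by heavy smoothing (downsample, 25x25 median, Gaussian sigma=0.5), Otsu
thresholding (tissue = darker class), a brightness-based border refinement
that removes mask pixels whose gray level is close to the background
(gL > mean_back + 0.5*std_back), and morphological cleaning (hole filling,
removal of small or non-compact components).  The result carries the tissue
area TA and the tight crop box used to restrict all downstream processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .io import BinaryMask, RGBImage

__all__ = [
    "BackgroundStats",
    "TissueRegion",
    "NoTissueError",
    "rgb_to_gray",
    "smooth_gray",
    "otsu_tissue_mask",
    "refine_border",
    "clean_mask",
    "segment_tissue",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


class NoTissueError(ValueError):
    """Raised when no tissue region can be found in an image."""


@dataclass
class BackgroundStats:
    mean_back: float
    std_back: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_back <= 255.0):
            raise ValueError("mean_back must lie in [0, 255]")
        if self.std_back < 0:
            raise ValueError("std_back must be non-negative")

    @property
    def threshold(self) -> float:
        return self.mean_back + 0.5 * self.std_back


@dataclass
class TissueRegion:
    """Binary tissue mask with its area TA and tight crop box."""

    mask: BinaryMask
    TA: int
    crop_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    @classmethod
    def from_mask(cls, mask: BinaryMask) -> "TissueRegion":
        px = mask.pixels
        if not px.any():
            raise NoTissueError("empty tissue mask")
        rows = np.flatnonzero(px.any(axis=1))
        cols = np.flatnonzero(px.any(axis=0))
        box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        return cls(mask=mask, TA=mask.area, crop_box=box)

    def cropped(self) -> BinaryMask:
        r0, c0, r1, c1 = self.crop_box
        return BinaryMask(self.mask.pixels[r0:r1, c0:c1], frame=self.mask.frame)


def rgb_to_gray(img: RGBImage) -> np.ndarray:
    """Standard luminance gray conversion, float64 in [0, 255]."""
    return img.pixels.astype(np.float64) @ _LUMA


def smooth_gray(
    img: RGBImage,
    downsample_limit: int = 5000,
    median_size: int = 25,
    gaussian_sigma: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Downsample, convert to gray and heavily smooth a slide image.

    The image is bilinearly downsampled so its larger dimension is at most
    ``downsample_limit`` (aspect ratio preserved), converted to luminance and
    filtered with a ``median_size`` square median filter followed by a
    Gaussian of ``gaussian_sigma``.  Returns (smoothed gray image, scale
    factor applied), scale <= 1.
    """
    h, w = img.shape
    scale = min(1.0, downsample_limit / max(h, w))
    gray = rgb_to_gray(img)
    if scale < 1.0:
        new_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
        gray = resize(gray, new_shape, order=1, anti_aliasing=False, preserve_range=True)
    smoothed = ndimage.median_filter(gray, size=median_size, mode="nearest")
    smoothed = ndimage.gaussian_filter(smoothed, sigma=gaussian_sigma, mode="nearest")
    return smoothed, scale


def otsu_tissue_mask(smoothed: np.ndarray, original_shape: tuple[int, int] | None = None) -> BinaryMask:
    """Otsu-threshold a smoothed gray image; tissue is the darker class.

    If ``original_shape`` is given the mask is rescaled back to that size by
    nearest-neighbor interpolation.
    """
    vals = np.unique(smoothed)
    if vals.size < 2:
        raise NoTissueError("constant image: no tissue/background separation possible")
    thr = threshold_otsu(smoothed)
    mask = smoothed < thr
    if original_shape is not None and mask.shape != tuple(original_shape):
        mask = resize(mask.astype(float), original_shape, order=0, preserve_range=True) > 0.5
    if not mask.any():
        raise NoTissueError("Otsu threshold produced an empty tissue mask")
    return BinaryMask(mask)


def background_stats(mask: BinaryMask, gray: np.ndarray) -> BackgroundStats:
    back = gray[~mask.pixels]
    if back.size == 0:
        raise ValueError("empty background: cannot estimate background statistics")
    return BackgroundStats(mean_back=float(back.mean()), std_back=float(back.std()))


def refine_border(
    mask: BinaryMask, gray: np.ndarray, stats: BackgroundStats | None = None
) -> BinaryMask:
    """Remove mask pixels whose gray level is background-like.

    Background statistics are taken over the mask complement (unless given),
    and every tissue pixel p with gL(p) > mean_back + 0.5*std_back is
    dropped.  Anti-extensive, and idempotent for fixed stats.
    """
    if mask.pixels.shape != gray.shape:
        raise ValueError("mask and gray image must share shape")
    if stats is None:
        stats = background_stats(mask, gray)
    keep = mask.pixels & ~(gray > stats.threshold)
    return BinaryMask(keep, frame=mask.frame)


def _boundary_edge_counts(labels: np.ndarray, n_comp: int) -> np.ndarray:
    """Perimeter of each labelled component as its count of exposed pixel edges."""
    perims = np.zeros(n_comp + 1, dtype=np.int64)
    padded = np.pad(labels, 1, mode="constant")
    for shift_axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=shift_axis)
        exposed = (padded > 0) & (padded != neighbor)
        perims += np.bincount(padded[exposed], minlength=n_comp + 1)
    return perims


def clean_mask(
    mask: BinaryMask,
    min_area_frac: float = 0.0005,
    min_compactness: float = 0.05,
    hole_area_frac: float = 0.01,
) -> TissueRegion:
    """Fill small holes, drop small/non-compact components, crop.

    Holes smaller than ``hole_area_frac`` of the current tissue area are
    filled.  A connected component is removed when its area is below
    ``min_area_frac`` of the whole image area or when its compactness
    4*pi*A/P^2 falls below ``min_compactness`` (spiculated filaments).
    """
    px = mask.pixels
    if not px.any():
        raise NoTissueError("empty mask")
    hole_limit = max(1, int(hole_area_frac * px.sum()))
    filled = morphology.remove_small_holes(px, max_size=hole_limit)
    labels, n_comp = measure.label(filled, connectivity=2, return_num=True)
    out = np.zeros_like(filled)
    area_limit = min_area_frac * px.shape[0] * px.shape[1]
    areas = np.bincount(labels.ravel())
    perims = _boundary_edge_counts(labels, n_comp)
    for lab in range(1, n_comp + 1):
        area = areas[lab]
        if area < area_limit:
            continue
        perim = perims[lab]
        # 4*pi*A/P^2 with P = boundary edge count: ~pi/4 for a square,
        # ~0.016 for a 1-px-wide 200-px filament
        compactness = 4.0 * np.pi * area / (perim * perim) if perim > 0 else 1.0
        if compactness < min_compactness:
            continue
        out[labels == lab] = True
    if not out.any():
        raise NoTissueError("all components removed during cleaning")
    return TissueRegion.from_mask(BinaryMask(out, frame=mask.frame))


def segment_tissue(
    img: RGBImage,
    downsample_limit: int = 5000,
    min_area_frac: float = 0.0005,
    min_compactness: float = 0.05,
    hole_area_frac: float = 0.01,
) -> TissueRegion:
    """Full tissue segmentation pipeline on one slide image."""
    smoothed, _ = smooth_gray(img, downsample_limit=downsample_limit)
    mask = otsu_tissue_mask(smoothed, original_shape=img.shape)
    gray = rgb_to_gray(img)
    refined = refine_border(mask, gray)
    if not refined.pixels.any():
        refined = mask  # refinement wiped everything: fall back to raw Otsu
    return clean_mask(
        refined,
        min_area_frac=min_area_frac,
        min_compactness=min_compactness,
        hole_area_frac=hole_area_frac,
    )
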