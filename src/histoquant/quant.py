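"""Marker-mask cleaning, densities, and minimum-distance histograms.

Marker density DM_T = A_M / TA is the fraction of the tissue area covered by
segmented marker pixels (reported as percent).  The spatial layout of a
marker relative to a structure of interest (basement membrane, nodule
border, ...) is summarized by the normalized histogram of each marker
pixel's Euclidean distance to the nearest border pixel, optionally limited
to a band around the border; histograms of a marker over an image set are
averaged bin-wise, and two markers' histograms are compared by histogram
intersection (sum of bin-wise minima, averaged over the two directions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import BinaryMask
from .tissue import TissueRegion

__all__ = [
    "MarkerSegmentation",
    "DistanceHistogram",
    "DensityResult",
    "clean_marker_mask",
    "marker_density",
    "min_distance_histogram",
    "mean_histogram",
    "histogram_intersection",
]

MIN_COMPONENT_PIXELS = 3  # components below this are noise/artifacts


@dataclass
class MarkerSegmentation:
    """Cleaned binary marker mask M with its area A_M."""

    M: BinaryMask
    A_M: int

    @classmethod
    def from_mask(cls, mask: BinaryMask) -> "MarkerSegmentation":
        return cls(M=mask, A_M=mask.area)


@dataclass
class DistanceHistogram:
    bin_width_px: float
    band_limit_px: float
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.bin_width_px <= 0:
            raise ValueError("bin_width_px must be positive")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be non-negative")

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    def bin_edges(self) -> np.ndarray:
        n = len(self.frequencies)
        return np.arange(n + 1) * self.bin_width_px


def clean_marker_mask(raw: BinaryMask) -> MarkerSegmentation:
    """Remove 8-connected components with fewer than 3 pixels.

    Such specks are too small to be stained structures and are typically
    noise or compression artifacts.  Idempotent and anti-extensive; an empty
    result is valid.
    """
    labels, n = measure.label(raw.pixels, connectivity=2, return_num=True)
    if n == 0:
        return MarkerSegmentation.from_mask(BinaryMask(raw.pixels.copy(), frame=raw.frame))
    counts = np.bincount(labels.ravel())
    keep = counts >= MIN_COMPONENT_PIXELS
    keep[0] = False
    cleaned = keep[labels]
    return MarkerSegmentation.from_mask(BinaryMask(cleaned, frame=raw.frame))


@dataclass
class DensityResult:
    DM: float  # fraction in [0, 1]
    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        return 100.0 * self.DM


def marker_density(
    seg: MarkerSegmentation, region: TissueRegion | BinaryMask
) -> DensityResult:
    """Marker density within the tissue region or a user ROI.

    For a :class:`TissueRegion` the denominator is TA and the marker mask is
    used as-is; for an ROI mask the markers are first clipped to the ROI and
    the denominator is the ROI area (DM_Ti = A_Mi / ROIA).
    """
    if isinstance(region, TissueRegion):
        denom = region.TA
        num = seg.A_M
    else:
        denom = region.area
        num = int((seg.M.pixels & region.pixels).sum())
    if denom == 0:
        raise ValueError("zero-area region: density undefined")
    return DensityResult(DM=num / denom, numerator=num, denominator=denom)


def min_distance_histogram(
    seg: MarkerSegmentation,
    border: BinaryMask,
    band_limit_px: float = math.inf,
    bin_width_px: float = 1.0,
) -> DistanceHistogram:
    """Histogram of marker-pixel distances to the nearest border pixel.

    Distances are exact Euclidean; marker pixels farther than
    ``band_limit_px`` from the border (outside the band) are excluded, and
    the histogram is normalized over the included pixels.  Bins are
    half-open [k*w, (k+1)*w).
    """
    if not border.pixels.any():
        raise ValueError("empty border mask")
    if seg.M.shape != border.shape:
        raise ValueError("marker and border masks must share shape")
    dist = ndimage.distance_transform_edt(~border.pixels)
    d = dist[seg.M.pixels]
    d = d[d <= band_limit_px]
    if d.size == 0:
        raise ValueError("no marker pixel within the band limit")
    bins = np.floor(d / bin_width_px).astype(np.int64)
    counts = np.bincount(bins)
    freqs = counts / counts.sum()
    return DistanceHistogram(
        bin_width_px=bin_width_px, band_limit_px=band_limit_px, frequencies=freqs
    )


def _check_same_binning(hists: list[DistanceHistogram]) -> tuple[float, float, int]:
    widths = {h.bin_width_px for h in hists}
    bands = {h.band_limit_px for h in hists}
    if len(widths) != 1 or len(bands) != 1:
        raise ValueError("histograms have mixed bin structures")
    n = max(len(h.frequencies) for h in hists)
    return widths.pop(), bands.pop(), n


def _padded(h: DistanceHistogram, n: int) -> np.ndarray:
    f = h.frequencies
    if len(f) < n:
        f = np.concatenate([f, np.zeros(n - len(f))])
    return f


def mean_histogram(hists: list[DistanceHistogram]) -> DistanceHistogram:
    """Bin-wise arithmetic mean of normalized histograms over an image set.

    Each image contributes equally regardless of its marker pixel count.
    """
    if not hists:
        raise ValueError("need at least one histogram")
    width, band, n = _check_same_binning(hists)
    mean = np.mean([_padded(h, n) for h in hists], axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    return DistanceHistogram(bin_width_px=width, band_limit_px=band, frequencies=mean)


def histogram_intersection(h1: DistanceHistogram, h2: DistanceHistogram) -> float:
    """Average of the two directed histogram-intersection measures.

    intersection(a -> b) = sum_i min(a_i, b_i) / sum_i b_i; for normalized
    inputs both directions equal sum(min) and so does the average.
    """
    _, _, n = _check_same_binning([h1, h2])
    a, b = _padded(h1, n), _padded(h2, n)
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("zero-mass histogram: intersection undefined")
    s = np.minimum(a, b).sum()
    return float(0.5 * (s / sa + s / sb))
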