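"""Per-pixel color/neighborhood feature vectors for the marker classifiers.

Each pixel is described by its raw RGB coordinates plus, for every configured
odd neighborhood size n, the mean, population standard deviation and local
range (max - min) of each RGB channel over the n-by-n window centered on the
pixel.  Borders use replicate padding.  The default size list [3, 7] yields a
21-dimensional vector; ``sizes=[7]`` yields the minimal 12-feature set.

Plane order (fixed, relied on by the classifier layers): R, G, B, then for
each size n in order: mu_nR, mu_nG, mu_nB, sigma_nR, sigma_nG, sigma_nB,
range_nR, range_nG, range_nB.  The first three planes double as the
3-dimensional RGB representation consumed by the KNN layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import RGBImage

__all__ = ["FeatureStack", "compute_feature_planes", "extract_vectors", "DEFAULT_SIZES"]

DEFAULT_SIZES: tuple[int, ...] = (3, 7)

_CHANNELS = "RGB"


@dataclass
class FeatureStack:
    """A (H, W, D) float64 stack of per-pixel feature planes."""

    planes: np.ndarray
    names: list[str]
    sizes: tuple[int, ...]

    @property
    def n_features(self) -> int:
        return self.planes.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[0], self.planes.shape[1]


def feature_names(sizes: Sequence[int]) -> list[str]:
    names = [f"{c}_p" for c in _CHANNELS]
    for n in sizes:
        names += [f"mu_{n}{c}" for c in _CHANNELS]
        names += [f"sigma_{n}{c}" for c in _CHANNELS]
        names += [f"range_{n}{c}" for c in _CHANNELS]
    return names


def compute_feature_planes(img: RGBImage, sizes: Sequence[int] = DEFAULT_SIZES) -> FeatureStack:
    """Compute all feature planes for an image.

    Means use a uniform (box) filter; sigma is the population standard
    deviation sqrt(E[x^2] - E[x]^2) clipped at zero; ranges use max/min
    filters.  All filters replicate the border pixel values.
    """
    sizes = tuple(int(n) for n in sizes)
    for n in sizes:
        if n < 3 or n % 2 == 0:
            raise ValueError(f"neighborhood sizes must be odd and >= 3, got {n}")
    rgb = img.pixels.astype(np.float64)
    ints = img.pixels.astype(np.int64)
    planes = [rgb[:, :, c] for c in range(3)]
    for n in sizes:
        kernel = np.ones(n, dtype=np.int64)
        mus, sigmas, ranges = [], [], []
        for c in range(3):
            ch = ints[:, :, c]
            # exact integer window sums (separable box kernel) keep the
            # derived statistics independent of position and tiling
            s1 = ndimage.correlate1d(ch, kernel, axis=0, mode="nearest")
            s1 = ndimage.correlate1d(s1, kernel, axis=1, mode="nearest")
            s2 = ndimage.correlate1d(ch * ch, kernel, axis=0, mode="nearest")
            s2 = ndimage.correlate1d(s2, kernel, axis=1, mode="nearest")
            nn = float(n * n)
            mu = s1 / nn
            sigma = np.sqrt(np.maximum(s2 / nn - mu * mu, 0.0))
            rng = (
                ndimage.maximum_filter(ch, size=n, mode="nearest")
                - ndimage.minimum_filter(ch, size=n, mode="nearest")
            ).astype(np.float64)
            mus.append(mu)
            sigmas.append(sigma)
            ranges.append(rng)
        planes += mus + sigmas + ranges
    stack = np.stack(planes, axis=-1)
    return FeatureStack(planes=stack, names=feature_names(sizes), sizes=sizes)


def extract_vectors(stack: FeatureStack, pixels: Sequence[tuple[int, int]]) -> np.ndarray:
    """Extract one feature vector per (row, col) coordinate, order preserved."""
    if len(pixels) == 0:
        return np.empty((0, stack.n_features), dtype=np.float64)
    coords = np.asarray(pixels, dtype=np.int64)
    h, w = stack.shape
    rows, cols = coords[:, 0], coords[:, 1]
    if (rows < 0).any() or (rows >= h).any() or (cols < 0).any() or (cols >= w).any():
        bad = coords[(rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)][0]
        raise IndexError(f"pixel coordinate {tuple(bad)} outside image of shape {(h, w)}")
    return stack.planes[rows, cols, :]
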