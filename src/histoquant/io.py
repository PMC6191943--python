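"""Image and mask I/O, tiling of oversized images, and multi-marker overlays.

Slide scans can exceed comfortable memory budgets, so images may be cut into
vertical strips (full-height column ranges) that are processed independently
and reassembled.  Strips carry an overlap margin so that per-pixel
neighborhood features computed per strip agree with whole-image computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RGBImage",
    "BinaryMask",
    "Tile",
    "TileSet",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "slice_tiles",
    "merge_tiles",
    "render_overlay",
    "DEFAULT_OVERLAY_COLORS",
]


@dataclass
class RGBImage:
    """An 8-bit RGB image with an optional physical resolution.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    resolution_um_per_px : float or None
        Physical pixel size, when known.  Purely informational; all
        computations are in pixel units unless stated otherwise.
    """

    pixels: np.ndarray
    resolution_um_per_px: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixel array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.resolution_um_per_px is not None and self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A boolean pixel mask tied to a coordinate frame.

    ``frame`` distinguishes masks living in an image's native grid
    (``"native"``) from masks resampled into a registered reference grid
    (``"registered"``).  Operations that combine masks require matching
    frames and shapes.
    """

    pixels: np.ndarray
    frame: str = "native"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")

    @property
    def area(self) -> int:
        """Number of true pixels (A(x) in the co-existence measures)."""
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Tile:
    image: RGBImage
    row_offset: int
    col_offset: int
    # core column range (absolute, half-open) that this tile owns on merge
    core_col_start: int
    core_col_stop: int


@dataclass
class TileSet:
    tiles: list[Tile]
    overlap_px: int
    source_shape: tuple[int, int] = field(default=(0, 0))


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer image to 8 bit by max-value division (rounded)."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        out = (arr.astype(np.uint64) * 255 + maxval // 2) // maxval
        return out.astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def read_image(path: str | Path) -> RGBImage:
    """Read a PNG/TIFF/JPEG image as 8-bit RGB.

    Grayscale inputs are replicated to three channels; higher-depth integer
    images are rescaled to 8 bit by dividing by their dtype's maximum value.
    An image with more than three channels is rejected (an alpha channel is
    silently discarded).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 1, 3 or 4 channels, got shape {arr.shape}")
    return RGBImage(_to_uint8(arr))


def write_image(path: str | Path, img: RGBImage) -> None:
    iio.imwrite(Path(path), img.pixels)


def read_mask(path: str | Path, frame: str = "native") -> BinaryMask:
    """Read a single-channel (or RGB) 0/255 mask image as a boolean mask."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return BinaryMask(arr > 127, frame=frame)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def slice_tiles(img: RGBImage, max_pixels: int, overlap_px: int = 3) -> TileSet:
    """Cut an image into full-height vertical strips of ≤ max_pixels each.

    Each strip's *core* column range partitions the image width; the stored
    strip additionally extends ``overlap_px`` columns on both sides (clipped
    at the borders) so neighborhood features match whole-image values.
    ``merge_tiles`` is the exact inverse.
    """
    if max_pixels <= 0:
        raise ValueError("max_pixels must be positive")
    if overlap_px < 0:
        raise ValueError("overlap_px must be non-negative")
    h, w = img.shape
    if max_pixels < h:
        raise ValueError(
            f"max_pixels={max_pixels} is smaller than one image column ({h} px)"
        )
    core_width = max(1, max_pixels // h)
    tiles: list[Tile] = []
    for start in range(0, w, core_width):
        stop = min(w, start + core_width)
        lo = max(0, start - overlap_px)
        hi = min(w, stop + overlap_px)
        tiles.append(
            Tile(
                image=RGBImage(img.pixels[:, lo:hi].copy(), img.resolution_um_per_px),
                row_offset=0,
                col_offset=lo,
                core_col_start=start,
                core_col_stop=stop,
            )
        )
    return TileSet(tiles=tiles, overlap_px=overlap_px, source_shape=(h, w))


def merge_tiles(tileset: TileSet) -> RGBImage:
    """Reassemble a TileSet into the original image (bit-exact)."""
    h, w = tileset.source_shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    res = None
    for t in tileset.tiles:
        a = t.core_col_start - t.col_offset
        b = t.core_col_stop - t.col_offset
        out[:, t.core_col_start : t.core_col_stop] = t.image.pixels[:, a:b]
        res = t.image.resolution_um_per_px
    return RGBImage(out, res)


DEFAULT_OVERLAY_COLORS: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0),
    (0, 255, 0),
    (0, 0, 255),
)


def render_overlay(
    masks: list[BinaryMask],
    colors: list[tuple[int, int, int]] | None = None,
    background: str = "black",
) -> RGBImage:
    """Combine marker masks additively into one color image.

    Pixels covered by several masks receive the clipped sum of the assigned
    colors, so with the default pure R/G/B palette two overlapped markers
    appear yellow/purple/cyan and all three together appear white.  Pixels in
    no mask take the background color (black by default, or white).
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    frame = masks[0].frame
    for m in masks[1:]:
        if m.shape != shape or m.frame != frame:
            raise ValueError("all masks must share shape and frame")
    if colors is None:
        if len(masks) > len(DEFAULT_OVERLAY_COLORS):
            raise ValueError("supply explicit colors for more than 3 masks")
        colors = list(DEFAULT_OVERLAY_COLORS[: len(masks)])
    if len(colors) != len(masks):
        raise ValueError("one color per mask required")
    acc = np.zeros(shape + (3,), dtype=np.int64)
    covered = np.zeros(shape, dtype=bool)
    for m, c in zip(masks, colors):
        acc[m.pixels] += np.asarray(c, dtype=np.int64)
        covered |= m.pixels
    out = np.clip(acc, 0, 255).astype(np.uint8)
    if background == "white":
        out[~covered] = 255
    elif background != "black":
        raise ValueError("background must be 'black' or 'white'")
    return RGBImage(out)
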