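"""Synthetic histology-like fixtures with exact ground truth.

Real HC/IHC slides show a darker tissue slice on a bright slide background,
stain-colored marker dots or clusters inside the tissue, and color
distractors (china-ink resection margins, blood cells, fold artifacts) whose
appearance mimics the stain.  This module renders simplified sections with
those ingredients from explicit color models, returning exact tissue and
marker masks plus per-class pixel annotations, so every downstream stage can
be tested against known truth.  Serial-section sets are produced by warping
one base tissue blob with known similarity transforms.

Everything is driven by a single integer seed; the same spec renders
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BinaryMask, RGBImage
from .registration import SimilarityTransform, apply_transform

__all__ = [
    "SpecError",
    "ColorModel",
    "Cluster",
    "MarkerLayout",
    "SyntheticSpec",
    "SectionSample",
    "generate_section",
    "annotations_from_samples",
    "generate_serial_set",
]


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class ColorModel:
    """Per-channel Gaussian color model, truncated at 4 sigma."""

    mean: tuple[float, float, float]
    sigma: float = 12.0

    def __post_init__(self) -> None:
        if not all(0 <= m <= 255 for m in self.mean):
            raise SpecError("color means must lie in [0, 255]")
        if self.sigma < 0:
            raise SpecError("sigma must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mean = np.asarray(self.mean, dtype=np.float64)
        draws = rng.normal(mean, self.sigma, size=(n, 3))
        draws = np.clip(draws, mean - 4 * self.sigma, mean + 4 * self.sigma)
        return np.clip(np.rint(draws), 0, 255).astype(np.uint8)

    def within_4sigma(self, colors: np.ndarray) -> np.ndarray:
        mean = np.asarray(self.mean, dtype=np.float64)
        lo = np.floor(np.clip(mean - 4 * self.sigma, 0, 255))
        hi = np.ceil(np.clip(mean + 4 * self.sigma, 0, 255))
        c = colors.astype(np.float64)
        return np.all((c >= lo - 0.5) & (c <= hi + 0.5), axis=-1)


@dataclass
class Cluster:
    center: tuple[int, int]  # (row, col)
    sd: float
    count: int


@dataclass
class MarkerLayout:
    """Where marker dots go: uniform over tissue, planted clusters, or both."""

    n_uniform: int = 0
    clusters: list[Cluster] = field(default_factory=list)
    dot_radius: int = 1
    explicit_centers: list[tuple[int, int]] | None = None


# study-condition defaults: marker stain reddish-brown, ink distractor a
# darker red-brown whose RG/B balance mimics the stain, shared sigma 12
MARKER_COLOR = ColorModel(mean=(180.0, 60.0, 50.0), sigma=12.0)
INK_COLOR = ColorModel(mean=(120.0, 60.0, 50.0), sigma=12.0)


@dataclass
class SyntheticSpec:
    height: int = 300
    width: int = 300
    background_gray: float = 240.0
    tissue_gray: float = 190.0
    noise_sigma: float = 4.0
    salt_pepper_rate: float = 1e-4
    marker_color: ColorModel = field(default_factory=lambda: MARKER_COLOR)
    ink_color: ColorModel = field(default_factory=lambda: INK_COLOR)
    markers: MarkerLayout = field(default_factory=lambda: MarkerLayout(n_uniform=120))
    n_ink_blobs: int = 3
    ink_radius: int = 3
    blob_radius_frac: float = 0.32
    seed: int = 0


@dataclass
class SectionSample:
    """One rendered section plus its exact ground truth."""

    image: RGBImage
    tissue_mask: BinaryMask
    marker_mask: BinaryMask
    marker_pixels: list[tuple[int, int]]
    critical_pixels: list[tuple[int, int]]  # distractor (ink) pixels
    negative_rects: list[tuple[int, int, int, int]]  # (r0, c0, r1, c1), half-open


def _tissue_blob(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth closed blob: an ellipse-ish region with wavy boundary radius."""
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    base_r = spec.blob_radius_frac * min(h, w)
    n_harm = 4
    amps = rng.uniform(0.02, 0.08, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    elong = rng.uniform(0.75, 1.0)
    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - cy, (cols - cx) * (1.0 / elong)
    radius = np.hypot(dy, dx)
    angle = np.arctan2(dy, dx)
    boundary = base_r * (
        1.0 + sum(a * np.cos((k + 1) * angle + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return radius <= boundary


def _disc_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= r * r
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp(mask: np.ndarray, centers: list[tuple[int, int]], radius: int) -> None:
    offs = _disc_offsets(radius)
    h, w = mask.shape
    for r, c in centers:
        rr = offs[:, 0] + r
        cc = offs[:, 1] + c
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[ok], cc[ok]] = True


def _place_markers(
    tissue: np.ndarray, layout: MarkerLayout, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Sample non-overlapping dot centers inside the tissue blob."""
    h, w = tissue.shape
    margin = ndimage.binary_erosion(
        tissue, structure=np.ones((3, 3)), iterations=layout.dot_radius + 1
    )
    allowed = margin.copy()
    centers: list[tuple[int, int]] = []
    # centers at Chebyshev distance >= 2r+2 leave a >=1 px gap between discs,
    # keeping dot components 8-disconnected
    sep = 2 * layout.dot_radius + 1

    def place_one(sampler, what: str) -> None:
        for _ in range(5000):
            r, c = sampler()
            if 0 <= r < h and 0 <= c < w and allowed[r, c]:
                centers.append((r, c))
                rr0, rr1 = max(0, r - sep), min(h, r + sep + 1)
                cc0, cc1 = max(0, c - sep), min(w, c + sep + 1)
                allowed[rr0:rr1, cc0:cc1] = False
                return
        raise SpecError(f"could not place {what}: tissue too crowded or too small")

    if layout.explicit_centers is not None:
        for r, c in layout.explicit_centers:
            if not (0 <= r < h and 0 <= c < w):
                raise SpecError(f"explicit marker center {(r, c)} outside canvas")
            centers.append((int(r), int(c)))
    else:
        allowed_idx = np.argwhere(margin)
        if allowed_idx.size == 0 and (layout.n_uniform or layout.clusters):
            raise SpecError("tissue blob too small to host markers")
        for cl in layout.clusters:
            r0, c0 = cl.center
            if not (0 <= r0 < h and 0 <= c0 < w):
                raise SpecError(f"cluster center {cl.center} outside canvas")
            if not tissue[r0, c0]:
                raise SpecError(f"cluster center {cl.center} outside the tissue blob")
            for _ in range(cl.count):
                place_one(
                    lambda: (
                        int(round(rng.normal(r0, cl.sd))),
                        int(round(rng.normal(c0, cl.sd))),
                    ),
                    f"cluster dot near {cl.center}",
                )
        for _ in range(layout.n_uniform):
            place_one(
                lambda: tuple(allowed_idx[rng.integers(len(allowed_idx))]),
                "uniform dot",
            )

    mask = np.zeros((h, w), dtype=bool)
    _stamp(mask, centers, layout.dot_radius)
    return centers, mask


def _place_ink(
    tissue: np.ndarray, spec: SyntheticSpec, forbidden: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """High-saturation ink blobs straddling the tissue border."""
    mask = np.zeros_like(tissue)
    if spec.n_ink_blobs == 0:
        return mask
    border = tissue & ~ndimage.binary_erosion(tissue, structure=np.ones((3, 3)), iterations=2)
    border_idx = np.argwhere(border)
    if border_idx.size == 0:
        return mask
    for _ in range(spec.n_ink_blobs):
        for _ in range(100):
            r, c = border_idx[rng.integers(len(border_idx))]
            blob = np.zeros_like(tissue)
            _stamp(blob, [(int(r), int(c))], spec.ink_radius)
            blob &= tissue
            if not (blob & forbidden).any():
                mask |= blob
                break
    return mask


def _find_negative_rects(
    occupied: np.ndarray,
    tissue: np.ndarray,
    rng: np.random.Generator,
    n_rects: int = 4,
    size: int = 20,
) -> list[tuple[int, int, int, int]]:
    """Rectangles free of marker/distractor pixels (obvious negatives).

    Half of the rectangles are forced fully inside the tissue so plain
    tissue texture is represented among the obvious negatives, the rest may
    fall anywhere (typically bright background).
    """
    h, w = occupied.shape
    pad = ndimage.binary_dilation(occupied, structure=np.ones((3, 3)), iterations=2)
    rects = []
    for k in range(n_rects):
        want_tissue = k < n_rects // 2
        for _ in range(500):
            r0 = int(rng.integers(0, max(1, h - size)))
            c0 = int(rng.integers(0, max(1, w - size)))
            window_clear = not pad[r0 : r0 + size, c0 : c0 + size].any()
            in_tissue = tissue[r0 : r0 + size, c0 : c0 + size].all()
            if window_clear and (in_tissue == want_tissue):
                rects.append((r0, c0, r0 + size, c0 + size))
                break
    return rects


def _render(
    spec: SyntheticSpec,
    tissue: np.ndarray,
    marker: np.ndarray,
    ink: np.ndarray,
    rng: np.random.Generator,
) -> RGBImage:
    h, w = tissue.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_gray
    img[tissue] = spec.tissue_gray
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if ink.any():
        img[ink] = spec.ink_color.sample(int(ink.sum()), rng)
    if marker.any():
        img[marker] = spec.marker_color.sample(int(marker.sum()), rng)
    if spec.salt_pepper_rate > 0:
        plain = ~(marker | ink)
        noise = (rng.random((h, w)) < spec.salt_pepper_rate) & plain
        idx = np.argwhere(noise)
        if len(idx):
            vals = rng.integers(0, 2, size=len(idx)) * 255
            img[idx[:, 0], idx[:, 1]] = vals[:, None]
    return RGBImage(img)


def _build_section(
    spec: SyntheticSpec,
    tissue: np.ndarray,
    layout: MarkerLayout,
    rng: np.random.Generator,
) -> SectionSample:
    centers, marker = _place_markers(tissue, layout, rng)
    marker &= tissue
    ink = _place_ink(tissue, spec, forbidden=marker, rng=rng)
    image = _render(spec, tissue, marker, ink, rng)
    rects = _find_negative_rects(marker | ink, tissue, rng)
    return SectionSample(
        image=image,
        tissue_mask=BinaryMask(tissue.copy()),
        marker_mask=BinaryMask(marker),
        marker_pixels=[tuple(x) for x in np.argwhere(marker)],
        critical_pixels=[tuple(x) for x in np.argwhere(ink)],
        negative_rects=rects,
    )


def generate_section(spec: SyntheticSpec) -> SectionSample:
    """Render one synthetic section with exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_blob(spec, rng)
    return _build_section(spec, tissue, spec.markers, rng)


def annotations_from_samples(
    samples: dict[str, SectionSample],
    n_marker: int = 150,
    n_critical: int = 150,
    n_halo: int = 150,
    seed: int = 0,
):
    """Build a training :class:`~histoquant.training.AnnotationSet` from truth.

    Emulates an expert annotation round: up to ``n_marker`` marker pixels and
    ``n_critical`` distractor (ink) pixels per image, the obvious-negative
    rectangles, and up to ``n_halo`` tissue pixels adjacent to marker dots.
    The halo pixels are annotated as critical not-markers: their own color is
    plain tissue but their neighborhood statistics mimic markers, which is
    exactly the kind of stain-like confusion critical negatives exist for.
    """
    from .training import AnnotationSet

    rng = np.random.default_rng(seed)
    ann = AnnotationSet()
    for name, s in samples.items():
        mk = s.marker_mask.pixels
        if s.marker_pixels:
            pick = rng.choice(len(s.marker_pixels), size=min(n_marker, len(s.marker_pixels)),
                              replace=False)
            ann.marker_pixels += [(name, *s.marker_pixels[k]) for k in np.sort(pick)]
        if s.critical_pixels:
            pick = rng.choice(len(s.critical_pixels), size=min(n_critical, len(s.critical_pixels)),
                              replace=False)
            ann.critical_negative_pixels += [(name, *s.critical_pixels[k]) for k in np.sort(pick)]
        halo = ndimage.binary_dilation(mk, structure=np.ones((3, 3)), iterations=2) & ~mk
        halo &= s.tissue_mask.pixels
        halo_idx = np.argwhere(halo)
        if len(halo_idx):
            pick = rng.choice(len(halo_idx), size=min(n_halo, len(halo_idx)), replace=False)
            ann.critical_negative_pixels += [
                (name, int(halo_idx[k][0]), int(halo_idx[k][1])) for k in np.sort(pick)
            ]
        ann.negative_rects += [(name, *r) for r in s.negative_rects]
    return ann


def generate_serial_set(
    spec: SyntheticSpec,
    n_sections: int,
    transforms: list[SimilarityTransform],
    marker_layouts: list[MarkerLayout] | None = None,
    share_markers: bool = False,
) -> tuple[list[SectionSample], list[SimilarityTransform]]:
    """Render a serial-section set: one base blob warped per section.

    Section i's tissue mask is the base blob warped by ``transforms[i]``;
    marker centers are laid out in the base frame and warped together with
    the tissue.  With ``share_markers=True`` the marker positions are sampled
    once and reused by every section (identical markers up to the warp), the
    configuration under which co-existence measures are exactly 100%.
    Returns the sections and the ground-truth transforms.
    """
    if n_sections < 2:
        raise SpecError("a serial set needs at least two sections")
    if len(transforms) != n_sections:
        raise SpecError("one transform per section required")
    if marker_layouts is None:
        marker_layouts = [spec.markers] * n_sections
    if len(marker_layouts) != n_sections:
        raise SpecError("one marker layout per section required")

    rng = np.random.default_rng(spec.seed)
    base = _tissue_blob(spec, rng)
    shared_marker: np.ndarray | None = None
    if share_markers:
        _, shared_marker = _place_markers(
            base, marker_layouts[0], np.random.default_rng(np.random.SeedSequence([spec.seed, 999]))
        )
    sections = []
    for i, (tf, layout) in enumerate(zip(transforms, marker_layouts)):
        sec_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + i]))
        if shared_marker is not None:
            marker_base = shared_marker
        else:
            _, marker_base = _place_markers(base, layout, sec_rng)
        warped_tissue = apply_transform(BinaryMask(base), tf, frame="native").pixels
        warped_marker = apply_transform(BinaryMask(marker_base), tf, frame="native").pixels
        if not warped_tissue.any():
            raise SpecError(f"transform {i} moved the tissue off-canvas")
        edge = np.zeros_like(warped_tissue)
        edge[0, :] = edge[-1, :] = True
        edge[:, 0] = edge[:, -1] = True
        if (warped_tissue & edge).any():
            raise SpecError(f"transform {i} moved the tissue off-canvas")
        warped_marker &= warped_tissue
        ink = _place_ink(warped_tissue, spec, forbidden=warped_marker, rng=sec_rng)
        image = _render(spec, warped_tissue, warped_marker, ink, sec_rng)
        rects = _find_negative_rects(warped_marker | ink, warped_tissue, sec_rng)
        sections.append(
            SectionSample(
                image=image,
                tissue_mask=BinaryMask(warped_tissue),
                marker_mask=BinaryMask(warped_marker),
                marker_pixels=[tuple(x) for x in np.argwhere(warped_marker)],
                critical_pixels=[tuple(x) for x in np.argwhere(ink)],
                negative_rects=rects,
            )
        )
    return sections, list(transforms)
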