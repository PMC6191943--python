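"""Shape-based alignment of serial tissue sections.

Serial sections are contiguous slices of one tissue block, each stained for a
different marker; before markers can be compared across sections, the tissue
masks must be brought into a common frame.  Sections are rigid glass-slide
preparations, so a similarity transform (translation + rotation + isotropic
scale) is fitted per section by a coarse-to-fine search maximizing binary
mask overlap.  Alignment quality of a whole set is summarized by the global
tissue-region overlap

    GTRO = 100 * A(T_1 ∩ ... ∩ T_n) / A(T_1 ∪ ... ∪ T_n)

i.e. the intersection-over-union of all tissue masks, in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage import transform as sktf

from .io import BinaryMask
from .tissue import TissueRegion

__all__ = [
    "SimilarityTransform",
    "RegisteredSet",
    "gtro",
    "apply_transform",
    "register_pair",
    "register_set",
]


@dataclass
class SimilarityTransform:
    """Similarity transform about the image center.

    Maps a point p = (col, row) to ``scale * R(theta) @ (p - c) + c + t``
    where c is the center of the image the transform is applied to and
    t = (tx, ty) in pixels (x = columns, y = rows).  theta is in degrees,
    counterclockwise in (x, y) coordinates.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def is_identity(self) -> bool:
        return self.tx == 0 and self.ty == 0 and self.theta_deg == 0 and self.scale == 1

    def inverse(self) -> "SimilarityTransform":
        th = math.radians(self.theta_deg)
        c, s = math.cos(-th), math.sin(-th)
        tx = -(c * self.tx - s * self.ty) / self.scale
        ty = -(s * self.tx + c * self.ty) / self.scale
        return SimilarityTransform(tx=tx, ty=ty, theta_deg=-self.theta_deg, scale=1.0 / self.scale)

    def to_skimage(self, shape: tuple[int, int]) -> sktf.SimilarityTransform:
        h, w = shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        th = math.radians(self.theta_deg)
        rot = sktf.SimilarityTransform(scale=self.scale, rotation=th)
        offset = center + np.array([self.tx, self.ty]) - rot(center[None, :])[0]
        return sktf.SimilarityTransform(scale=self.scale, rotation=th, translation=offset)

    def as_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta_deg": self.theta_deg, "scale": self.scale}


def apply_transform(
    mask: BinaryMask,
    tf: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
    frame: str = "registered",
) -> BinaryMask:
    """Warp a binary mask by a forward similarity transform.

    Nearest-neighbor resampling preserves binarity; areas are preserved only
    approximately, so pixel counts are always re-measured after warping.
    """
    shape = output_shape or mask.shape
    if tf.is_identity and shape == mask.shape:
        return BinaryMask(mask.pixels.copy(), frame=frame)
    sk = tf.to_skimage(mask.shape)
    warped = sktf.warp(
        mask.pixels.astype(np.float32), sk.inverse, order=0, output_shape=shape, cval=0.0
    )
    return BinaryMask(warped > 0.5, frame=frame)


def gtro(masks: list[BinaryMask] | list[np.ndarray]) -> float:
    """Global tissue-region overlap: 100 * |∩ masks| / |∪ masks|."""
    arrays = [m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool) for m in masks]
    if len(arrays) < 2:
        raise ValueError("GTRO needs at least two masks")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all masks must share the same shape")
    inter = arrays[0].copy()
    union = arrays[0].copy()
    for a in arrays[1:]:
        inter &= a
        union |= a
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("empty union: GTRO undefined")
    return 100.0 * int(inter.sum()) / n_union


def _overlap(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Dice coefficient between two boolean arrays."""
    denom = fixed.sum() + moving.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(fixed, moving).sum() / denom


def _downscale(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    hh, ww = h // 2 * 2, w // 2 * 2
    m = mask[:hh, :ww].reshape(hh // 2, 2, ww // 2, 2)
    return m.sum(axis=(1, 3)) >= 2


def _centroid_xy(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.array([cols.mean(), rows.mean()])


def _orientation_deg(mask: np.ndarray) -> float:
    # regionprops orientation: angle of major axis vs rows; convert to (x,y) ccw
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        return 0.0
    return math.degrees(props[0].orientation)


def _score(fixed: np.ndarray, moving: np.ndarray, tf: SimilarityTransform) -> float:
    warped = apply_transform(BinaryMask(moving), tf, output_shape=fixed.shape)
    return _overlap(fixed, warped.pixels)


def _coordinate_descent(
    fixed: np.ndarray,
    moving: np.ndarray,
    tf: SimilarityTransform,
    steps: tuple[float, float, float],
    min_steps: tuple[float, float, float],
    scale_bounds: tuple[float, float],
) -> tuple[SimilarityTransform, float]:
    """Greedy local search over (tx, ty, theta, scale) maximizing Dice."""
    params = [tf.tx, tf.ty, tf.theta_deg, tf.scale]
    step_t, step_th, step_s = steps
    best = _score(fixed, moving, SimilarityTransform(*params))
    while True:
        improved = False
        for idx, step in ((0, step_t), (1, step_t), (2, step_th), (3, step_s)):
            for delta in (step, -step):
                trial = list(params)
                trial[idx] += delta
                if idx == 3 and not (scale_bounds[0] <= trial[3] <= scale_bounds[1]):
                    continue
                s = _score(fixed, moving, SimilarityTransform(*trial))
                if s > best + 1e-12:
                    best = s
                    params = trial
                    improved = True
        if not improved:
            if step_t <= min_steps[0] and step_th <= min_steps[1] and step_s <= min_steps[2]:
                break
            step_t = max(min_steps[0], step_t / 2)
            step_th = max(min_steps[1], step_th / 2)
            step_s = max(min_steps[2], step_s / 2)
    return SimilarityTransform(*params), best


def register_pair(
    fixed: TissueRegion | BinaryMask,
    moving: TissueRegion | BinaryMask,
    coarse_limit: int = 256,
    scale_bounds: tuple[float, float] = (0.8, 1.25),
) -> SimilarityTransform:
    """Find the similarity transform aligning ``moving`` onto ``fixed``.

    Multiscale strategy: both masks are halved until the larger dimension is
    at most ``coarse_limit``; at the coarsest level the search is initialized
    from centroid alignment plus the principal-axis angle difference, refined
    by greedy coordinate descent on mask Dice, and the estimate is propagated
    up the pyramid with progressively finer steps.  If the final transform
    does not improve on identity at full resolution, identity is returned.
    """
    fpx = fixed.mask.pixels if isinstance(fixed, TissueRegion) else fixed.pixels
    mpx = moving.mask.pixels if isinstance(moving, TissueRegion) else moving.pixels
    if fpx.sum() < 2 or mpx.sum() < 2:
        raise ValueError("degenerate mask: cannot register")

    pyramid = [(fpx, mpx)]
    while max(pyramid[-1][0].shape) > coarse_limit:
        f, m = pyramid[-1]
        pyramid.append((_downscale(f), _downscale(m)))
    n_levels = len(pyramid)

    # --- coarsest-level initialization ---
    f, m = pyramid[-1]
    dtheta = _orientation_deg(f) - _orientation_deg(m)
    candidates = []
    for th in (0.0, dtheta, dtheta + 90, dtheta - 90):
        cm, cf = _centroid_xy(m), _centroid_xy(f)
        center = np.array([(m.shape[1] - 1) / 2.0, (m.shape[0] - 1) / 2.0])
        rad = math.radians(th)
        rot = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
        t = cf - (rot @ (cm - center) + center)
        candidates.append(SimilarityTransform(tx=float(t[0]), ty=float(t[1]), theta_deg=th))
    best_tf = max(candidates, key=lambda tf: _score(f, m, tf))

    best_tf, _ = _coordinate_descent(
        f, m, best_tf, steps=(4.0, 4.0, 0.02), min_steps=(0.5, 0.25, 0.005),
        scale_bounds=scale_bounds,
    )

    # --- propagate up the pyramid ---
    for level in range(n_levels - 2, -1, -1):
        f, m = pyramid[level]
        best_tf = SimilarityTransform(
            tx=best_tf.tx * 2, ty=best_tf.ty * 2, theta_deg=best_tf.theta_deg, scale=best_tf.scale
        )
        best_tf, _ = _coordinate_descent(
            f, m, best_tf, steps=(2.0, 1.0, 0.01), min_steps=(0.25, 0.1, 0.002),
            scale_bounds=scale_bounds,
        )

    # --- identity guard at full resolution ---
    if _score(fpx, mpx, best_tf) < _overlap(fpx, mpx):
        return SimilarityTransform()
    return best_tf


@dataclass
class RegisteredSet:
    """Outcome of registering a serial-section set to one reference."""

    reference_index: int
    transforms: list[SimilarityTransform]
    tissue_masks: list[BinaryMask]  # registered frame
    marker_masks: list[BinaryMask | None]  # registered frame
    GTRO_before: float
    GTRO_after: float
    shape: tuple[int, int] = field(default=(0, 0))


def register_set(
    sections: list[tuple[TissueRegion, BinaryMask | None]],
    reference_index: int = 0,
) -> RegisteredSet:
    """Register every section's tissue mask to the reference section.

    Each non-reference section gets one similarity transform, applied to both
    its tissue mask and (if present) its marker mask.  Registration never
    worsens the set's GTRO: if it would, all transforms fall back to identity.
    """
    if len(sections) < 2:
        raise ValueError("need at least two sections")
    ref_tissue = sections[reference_index][0]
    ref_shape = ref_tissue.mask.shape
    for i, (tr, _) in enumerate(sections):
        if tr.mask.shape != ref_shape:
            raise ValueError(f"section {i}: all sections must share a canvas shape")

    raw_masks = [tr.mask for tr, _ in sections]
    before = gtro(raw_masks)

    transforms: list[SimilarityTransform] = []
    for i, (tr, _) in enumerate(sections):
        if i == reference_index:
            transforms.append(SimilarityTransform())
            continue
        try:
            transforms.append(register_pair(ref_tissue, tr))
        except ValueError as exc:
            raise ValueError(f"registration failed for section {i}: {exc}") from exc

    reg_tissue = [
        apply_transform(tr.mask, tf, output_shape=ref_shape)
        for (tr, _), tf in zip(sections, transforms)
    ]
    after = gtro(reg_tissue)
    if after < before:  # global guard: never worsen the set overlap
        transforms = [SimilarityTransform() for _ in sections]
        reg_tissue = [BinaryMask(tr.mask.pixels.copy(), frame="registered") for tr, _ in sections]
        after = before

    reg_markers: list[BinaryMask | None] = []
    for (_, mk), tf in zip(sections, transforms):
        if mk is None:
            reg_markers.append(None)
        else:
            reg_markers.append(apply_transform(mk, tf, output_shape=ref_shape))

    return RegisteredSet(
        reference_index=reference_index,
        transforms=transforms,
        tissue_masks=reg_tissue,
        marker_masks=reg_markers,
        GTRO_before=before,
        GTRO_after=after,
        shape=ref_shape,
    )
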