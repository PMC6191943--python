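"""Training annotations, training-set assembly, and cost matrices.

Training pixels come in three classes: *marker* pixels (positives, label 1),
*critical not-marker* pixels (negatives whose color mimics the stain: ink,
blood cells, folds), and rectangular areas of *obvious* not-marker pixels.
A typical annotation round yields roughly 150 positives, 150 criticals and
15000 obvious negatives, i.e. a positive:negative ratio at or below 1/50 —
the cost matrices below compensate for that imbalance by charging more for
mistakes on the minority class.

The annotation file is a CSV with header ``image,kind,row,col,row1,col1``:
``kind`` is ``marker``/``critical`` (row, col used; last two columns empty)
or ``rect`` (half-open rectangle [row,row1) x [col,col1) of obvious
negatives).  Coordinates are 0-based, row-major.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureStack, extract_vectors

__all__ = [
    "AnnotationSet",
    "TrainingSet",
    "AnnotationError",
    "UnusableTrainingError",
    "load_annotations",
    "save_annotations",
    "assemble",
    "cost_matrix",
    "knn_cost_matrix",
    "class_weights_from_cost",
]

logger = logging.getLogger(__name__)

Pixel = tuple[str, int, int]  # (image id, row, col)
Rect = tuple[str, int, int, int, int]  # (image id, row0, col0, row1, col1)


class AnnotationError(ValueError):
    """Invalid or inconsistent annotation record."""


class UnusableTrainingError(ValueError):
    """A training set with an empty positive or negative pool."""


@dataclass
class AnnotationSet:
    marker_pixels: list[Pixel] = field(default_factory=list)
    critical_negative_pixels: list[Pixel] = field(default_factory=list)
    negative_rects: list[Rect] = field(default_factory=list)

    def validate(self, image_shapes: dict[str, tuple[int, int]]) -> None:
        def check_pixel(rec: Pixel, kind: str) -> None:
            img, r, c = rec
            if img not in image_shapes:
                raise AnnotationError(f"{kind} record {rec}: unknown image {img!r}")
            h, w = image_shapes[img]
            if not (0 <= r < h and 0 <= c < w):
                raise AnnotationError(f"{kind} record {rec}: coordinate outside {h}x{w} image")

        for rec in self.marker_pixels:
            check_pixel(rec, "marker")
        for rec in self.critical_negative_pixels:
            check_pixel(rec, "critical")
        for rec in self.negative_rects:
            img, r0, c0, r1, c1 = rec
            if img not in image_shapes:
                raise AnnotationError(f"rect record {rec}: unknown image {img!r}")
            h, w = image_shapes[img]
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise AnnotationError(f"rect record {rec}: degenerate or out-of-range rectangle")
        overlap = set(self.marker_pixels) & set(self.critical_negative_pixels)
        if overlap:
            raise AnnotationError(
                f"pixel annotated as both marker and critical not-marker: {sorted(overlap)[:3]}"
            )

    def obvious_negative_pixels(self) -> list[Pixel]:
        """Expand rectangles to pixels, excluding annotated marker/critical pixels."""
        claimed = set(self.marker_pixels) | set(self.critical_negative_pixels)
        out: list[Pixel] = []
        for img, r0, c0, r1, c1 in self.negative_rects:
            for r in range(r0, r1):
                for c in range(c0, c1):
                    rec = (img, r, c)
                    if rec not in claimed:
                        out.append(rec)
        return out


_HEADER = ["image", "kind", "row", "col", "row1", "col1"]


def load_annotations(
    path: str | Path, image_shapes: dict[str, tuple[int, int]] | None = None
) -> AnnotationSet:
    """Load an annotation CSV; validates against image shapes when given."""
    ann = AnnotationSet()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader):
            kind = (row.get("kind") or "").strip()
            img = (row.get("image") or "").strip()
            try:
                if kind == "marker":
                    ann.marker_pixels.append((img, int(row["row"]), int(row["col"])))
                elif kind == "critical":
                    ann.critical_negative_pixels.append((img, int(row["row"]), int(row["col"])))
                elif kind == "rect":
                    ann.negative_rects.append(
                        (img, int(row["row"]), int(row["col"]), int(row["row1"]), int(row["col1"]))
                    )
                else:
                    raise AnnotationError(f"line {i + 2}: unknown kind {kind!r}")
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, AnnotationError):
                    raise
                raise AnnotationError(f"line {i + 2}: malformed record {row}") from exc
    if image_shapes is not None:
        ann.validate(image_shapes)
    else:
        overlap = set(ann.marker_pixels) & set(ann.critical_negative_pixels)
        if overlap:
            raise AnnotationError(
                f"pixel annotated as both marker and critical not-marker: {sorted(overlap)[:3]}"
            )
    return ann


def save_annotations(path: str | Path, ann: AnnotationSet) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for img, r, c in ann.marker_pixels:
            writer.writerow([img, "marker", r, c, "", ""])
        for img, r, c in ann.critical_negative_pixels:
            writer.writerow([img, "critical", r, c, "", ""])
        for img, r0, c0, r1, c1 in ann.negative_rects:
            writer.writerow([img, "rect", r0, c0, r1, c1])


@dataclass
class TrainingSet:
    """Labelled feature pools for the cascade.  Label 1 = marker (positive)."""

    positives: np.ndarray
    critical_negatives: np.ndarray
    obvious_negatives: np.ndarray

    @property
    def Npos(self) -> int:
        return len(self.positives)

    @property
    def Ncrit(self) -> int:
        return len(self.critical_negatives)

    @property
    def Nneg(self) -> int:
        return len(self.obvious_negatives)

    @property
    def imbalance_ratio(self) -> float:
        return self.Npos / (self.Nneg + self.Ncrit)


def assemble(ann: AnnotationSet, planes_by_image: dict[str, FeatureStack]) -> TrainingSet:
    """Extract feature vectors for every annotated pixel, grouped by class."""

    def grab(pixels: list[Pixel]) -> np.ndarray:
        by_img: dict[str, list[tuple[int, int]]] = {}
        order: list[tuple[str, int]] = []
        for img, r, c in pixels:
            if img not in planes_by_image:
                raise AnnotationError(f"no feature planes for image {img!r}")
            by_img.setdefault(img, []).append((r, c))
        chunks = [
            extract_vectors(planes_by_image[img], coords) for img, coords in by_img.items()
        ]
        if not chunks:
            n_feat = next(iter(planes_by_image.values())).n_features if planes_by_image else 0
            return np.empty((0, n_feat))
        return np.vstack(chunks)

    ts = TrainingSet(
        positives=grab(ann.marker_pixels),
        critical_negatives=grab(ann.critical_negative_pixels),
        obvious_negatives=grab(ann.obvious_negative_pixels()),
    )
    if ts.Npos == 0:
        raise UnusableTrainingError("no positive (marker) training pixels")
    if ts.Nneg + ts.Ncrit == 0:
        raise UnusableTrainingError("no negative training pixels")
    if ts.Ncrit == 0:
        logger.warning("no critical not-marker pixels annotated; stain-like distractors "
                       "may produce false positives")
    logger.info(
        "training set: Npos=%d Ncrit=%d Nneg=%d (pos:neg ratio %.4f)",
        ts.Npos, ts.Ncrit, ts.Nneg, ts.imbalance_ratio,
    )
    return ts


def cost_matrix(Npos: int, Nneg: int, Ncrit: int) -> np.ndarray:
    """Misclassification cost matrix for the cost-sensitive DT/SVM layers.

    Rows index the true class (0 = not-marker, 1 = marker), columns the
    predicted class.  Cost(predicted 1 | true 0) = 1 - (Nneg+Ncrit)/N and
    Cost(predicted 0 | true 1) = 1 - Npos/N with N the total count, so the
    minority class always carries the larger misclassification cost and the
    two off-diagonals sum to 1.
    """
    if Npos < 0 or Nneg < 0 or Ncrit < 0:
        raise ValueError("counts must be non-negative")
    total = Npos + Nneg + Ncrit
    if total == 0:
        raise ValueError("at least one training sample required")
    c01 = 1.0 - (Nneg + Ncrit) / total  # true 0 predicted 1
    c10 = 1.0 - Npos / total  # true 1 predicted 0
    return np.array([[0.0, c01], [c10, 0.0]])


def knn_cost_matrix() -> np.ndarray:
    """The KNN layer is not cost-sensitive: unit off-diagonal costs."""
    return np.array([[0.0, 1.0], [1.0, 0.0]])


def class_weights_from_cost(cost: np.ndarray, present_classes=(0, 1)) -> dict[int, float]:
    """Class weights realizing a 2x2 cost matrix as expected-loss weighting.

    The weight of class t is the cost of misclassifying a true-t sample.
    Zero weights are floored at a tiny epsilon so degenerate single-class
    fits remain possible.
    """
    weights = {0: float(cost[0, 1]), 1: float(cost[1, 0])}
    eps = 1e-12
    return {k: max(v, eps) for k, v in weights.items() if k in present_classes}
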