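"""The four-layer stacked marker-pixel classifier.

Layers, in order: two cost-sensitive decision trees, one cost-sensitive
RBF-kernel SVM, and one plain 3-nearest-neighbor classifier working on raw
RGB only.  Applied as a rejection cascade: each layer discards pixels it
labels not-marker and forwards the surviving candidates, so the final
acceptance set is the intersection of the four layers' acceptance sets.

Training uses hard-negative mining: each layer after the first sees all
positives, all critical negatives, and only those obvious negatives that the
previous layer misclassified as marker (false positives).  This shrinks the
huge obvious-negative pool to the informative samples.  Cost-sensitivity is
realized as class weights proportional to the cost-matrix off-diagonals,
an equivalent expected-loss formulation.
"""

from __future__ import annotations

import logging
import math
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import DEFAULT_SIZES, compute_feature_planes
from .io import BinaryMask, RGBImage, slice_tiles
from .tissue import TissueRegion
from .training import TrainingSet, class_weights_from_cost, cost_matrix, knn_cost_matrix

__all__ = [
    "CascadeModel",
    "LayerInfo",
    "train_dt_cv",
    "train_svm_cv",
    "mine_hard_negatives",
    "train_cascade",
    "apply_cascade",
    "apply_cascade_tiled",
    "classify_pixels",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

LAYER_NAMES = ("DT1", "DT2", "SVM", "KNN3")


class _AcceptAll:
    """Degenerate layer used when a layer is left without negatives."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.ones(len(X), dtype=int)


@dataclass
class LayerInfo:
    name: str
    cost: np.ndarray
    n_pos: int
    n_crit: int
    n_obvious: int
    validation_accuracy: float | None = None


@dataclass
class CascadeModel:
    layers: list  # estimators, in LAYER_NAMES order
    info: list[LayerInfo]
    feature_sizes: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.layers) != 4:
            raise ValueError("a cascade has exactly four layers")


def _stack(*arrays: np.ndarray) -> np.ndarray:
    parts = [a for a in arrays if len(a)]
    if not parts:
        return np.empty((0, arrays[0].shape[1] if arrays and arrays[0].ndim == 2 else 0))
    return np.vstack(parts)


def _fold_counts(n_pos: int, n_neg: int, folds: int) -> tuple[int, int]:
    """Per-fold training counts: ceil(Npos/folds) positives and
    min(ceil(Nneg/folds), 5*Npos) negatives."""
    return math.ceil(n_pos / folds), min(math.ceil(n_neg / folds), 5 * n_pos)


def _cv_select(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    folds: int,
    rng: np.random.Generator,
    fit_one,
    max_retries: int = 5,
):
    """Shared fold-construction/selection machinery for the DT and SVM layers.

    Builds ``folds`` candidate classifiers, each trained on a random subset
    of each class (per-fold counts above) and validated on the remaining
    pixels with plain accuracy; the candidate with maximum validation
    accuracy wins (first on ties).  ``fit_one(X, y, seed)`` may return one
    estimator or a list of (estimator, tag) for an inner hyperparameter grid.
    """
    n_pos, n_neg = len(X_pos), len(X_neg)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty for cross-validated training")
    k_pos, k_neg = _fold_counts(n_pos, n_neg, folds)
    for attempt in range(max_retries):
        candidates = []
        retry = False
        for _ in range(folds):
            pos_idx = rng.permutation(n_pos)
            neg_idx = rng.permutation(n_neg)
            tr_p, va_p = pos_idx[:k_pos], pos_idx[k_pos:]
            tr_n, va_n = neg_idx[:k_neg], neg_idx[k_neg:]
            if len(tr_p) == 0 or len(tr_n) == 0:
                retry = True
                break
            X_tr = np.vstack([X_pos[tr_p], X_neg[tr_n]])
            y_tr = np.concatenate([np.ones(len(tr_p), int), np.zeros(len(tr_n), int)])
            if len(va_p) + len(va_n) == 0:
                retry = True
                break
            X_va = _stack(X_pos[va_p], X_neg[va_n])
            y_va = np.concatenate([np.ones(len(va_p), int), np.zeros(len(va_n), int)])
            fitted = fit_one(X_tr, y_tr, int(rng.integers(2**31)))
            if not isinstance(fitted, list):
                fitted = [fitted]
            for est in fitted:
                acc = float((est.predict(X_va) == y_va).mean())
                candidates.append((acc, est))
        if retry:
            continue
        best_acc, best = candidates[0]
        for acc, est in candidates[1:]:
            if acc > best_acc:
                best_acc, best = acc, est
        return best, best_acc
    raise ValueError(
        f"could not build valid folds after {max_retries} attempts "
        f"(Npos={n_pos}, Nneg={n_neg}, folds={folds})"
    )


def train_dt_cv(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    cost: np.ndarray,
    folds: int = 10,
    rng: np.random.Generator | None = None,
):
    """Train a cost-sensitive decision tree by fold-wise candidate selection."""
    rng = rng or np.random.default_rng(0)
    weights = class_weights_from_cost(cost)

    def fit_one(X, y, seed):
        w = {k: v for k, v in weights.items() if k in np.unique(y)}
        return DecisionTreeClassifier(class_weight=w, random_state=seed).fit(X, y)

    return _cv_select(X_pos, X_neg, folds, rng, fit_one)


def train_svm_cv(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    cost: np.ndarray,
    folds: int = 2,
    rng: np.random.Generator | None = None,
    C_grid: tuple[float, ...] = (1.0, 10.0, 100.0),
    gamma_grid: tuple = ("scale", 0.01, 0.1),
):
    """Train a cost-sensitive RBF SVM; C/gamma chosen inside the 2-fold CV."""
    rng = rng or np.random.default_rng(0)
    weights = class_weights_from_cost(cost)

    def fit_one(X, y, seed):
        w = {k: v for k, v in weights.items() if k in np.unique(y)}
        return [
            SVC(kernel="rbf", C=C, gamma=g, class_weight=w, random_state=seed).fit(X, y)
            for C in C_grid
            for g in gamma_grid
        ]

    return _cv_select(X_pos, X_neg, folds, rng, fit_one)


def mine_hard_negatives(model, X_neg: np.ndarray) -> np.ndarray:
    """Keep exactly the negatives the model misclassifies as marker."""
    if len(X_neg) == 0:
        return X_neg
    pred = model.predict(X_neg)
    return X_neg[np.asarray(pred) == 1]


def train_cascade(
    ts: TrainingSet,
    feature_sizes: tuple[int, ...] = DEFAULT_SIZES,
    seed: int = 0,
    folds_dt: int = 10,
    folds_svm: int = 2,
    svm_negative_cap: int = 20,
) -> CascadeModel:
    """Train DT1 -> DT2 -> SVM -> KNN3 with forward hard-negative mining.

    DT1 sees all negatives; DT2 sees criticals + DT1's false-positive obvious
    negatives; the SVM sees criticals + DT2's surviving obvious negatives
    (capped at ``svm_negative_cap * Npos`` by seeded subsampling); the KNN
    sees criticals + the obvious negatives that survived all three layers,
    in RGB coordinates only.  A layer left with no negatives at all degrades
    to accept-all with a warning.
    """
    rng = np.random.default_rng(seed)
    pos, crit, obv = ts.positives, ts.critical_negatives, ts.obvious_negatives
    layers, info = [], []

    def dt_layer(name: str, obvious: np.ndarray):
        cost = cost_matrix(len(pos), len(obvious), len(crit))
        negs = _stack(crit, obvious)
        if len(negs) == 0:
            logger.warning("%s: no negatives left; layer accepts everything", name)
            est, acc = _AcceptAll(), None
        else:
            est, acc = train_dt_cv(pos, negs, cost, folds=folds_dt, rng=rng)
        layers.append(est)
        info.append(LayerInfo(name, cost, len(pos), len(crit), len(obvious), acc))
        return est

    dt1 = dt_layer("DT1", obv)
    obv1 = mine_hard_negatives(dt1, obv)

    dt2 = dt_layer("DT2", obv1)
    obv2 = mine_hard_negatives(dt2, obv1)

    # SVM layer, with a cap on obvious negatives to bound the fit cost
    cap = svm_negative_cap * len(pos)
    if len(obv2) > cap:
        keep = rng.choice(len(obv2), size=cap, replace=False)
        obv2_train = obv2[np.sort(keep)]
    else:
        obv2_train = obv2
    cost_svm = cost_matrix(len(pos), len(obv2_train), len(crit))
    negs_svm = _stack(crit, obv2_train)
    if len(negs_svm) == 0:
        logger.warning("SVM: no negatives left; layer accepts everything")
        svm, acc_svm = _AcceptAll(), None
    else:
        svm, acc_svm = train_svm_cv(pos, negs_svm, cost_svm, folds=folds_svm, rng=rng)
    layers.append(svm)
    info.append(LayerInfo("SVM", cost_svm, len(pos), len(crit), len(obv2_train), acc_svm))
    obv3 = mine_hard_negatives(svm, obv2)

    # KNN layer: plain 3-NN on RGB coordinates only
    X_knn = _stack(pos[:, :3], crit[:, :3] if len(crit) else crit, obv3[:, :3] if len(obv3) else obv3)
    y_knn = np.concatenate(
        [np.ones(len(pos), int), np.zeros(len(crit) + len(obv3), int)]
    )
    k = min(3, len(X_knn))
    knn = KNeighborsClassifier(n_neighbors=k).fit(X_knn, y_knn)
    layers.append(knn)
    info.append(LayerInfo("KNN3", knn_cost_matrix(), len(pos), len(crit), len(obv3), None))

    return CascadeModel(layers=layers, info=info, feature_sizes=tuple(feature_sizes), seed=seed)


def classify_pixels(model: CascadeModel, X: np.ndarray, upto_layer: int | None = None) -> np.ndarray:
    """Run feature vectors through the rejection cascade.

    Returns a boolean array: True where every evaluated layer accepted the
    pixel.  ``upto_layer`` limits evaluation to the first k layers (used by
    the layer-intersection checks).
    """
    n = len(X)
    alive = np.ones(n, dtype=bool)
    n_layers = len(model.layers) if upto_layer is None else upto_layer
    for li in range(n_layers):
        if not alive.any():
            break
        est = model.layers[li]
        idx = np.flatnonzero(alive)
        feats = X[idx, :3] if model.info[li].name == "KNN3" else X[idx]
        pred = np.asarray(est.predict(feats))
        alive[idx[pred != 1]] = False
    return alive


def _tissue_pixels(tissue: TissueRegion | BinaryMask) -> np.ndarray:
    mask = tissue.mask if isinstance(tissue, TissueRegion) else tissue
    return mask.pixels


def apply_cascade(
    model: CascadeModel, img: RGBImage, tissue: TissueRegion | BinaryMask
) -> BinaryMask:
    """Classify every tissue pixel of an image; returns the raw marker mask.

    Pixels outside the tissue mask are never evaluated and are negative by
    definition.  The returned mask is uncleaned (see
    :func:`histoquant.quant.clean_marker_mask` for the <3 px filter).
    """
    tmask = _tissue_pixels(tissue)
    if tmask.shape != img.shape:
        raise ValueError("tissue mask and image shapes differ")
    out = np.zeros(img.shape, dtype=bool)
    idx = np.argwhere(tmask)
    if len(idx) == 0:
        return BinaryMask(out)
    stack = compute_feature_planes(img, model.feature_sizes)
    expected = stack.n_features
    for est, li in zip(model.layers, model.info):
        n_in = getattr(est, "n_features_in_", None)
        want = 3 if li.name == "KNN3" else expected
        if n_in is not None and n_in != want:
            raise ValueError(
                f"feature configuration mismatch: layer {li.name} expects {n_in} features, "
                f"image yields {want} (model sizes {model.feature_sizes})"
            )
    X = stack.planes[idx[:, 0], idx[:, 1], :]
    accepted = classify_pixels(model, X)
    out[idx[accepted, 0], idx[accepted, 1]] = True
    return BinaryMask(out)


def apply_cascade_tiled(
    model: CascadeModel,
    img: RGBImage,
    tissue: TissueRegion | BinaryMask,
    max_pixels: int,
) -> BinaryMask:
    """Tile-wise cascade application; equals whole-image application.

    Tiles overlap by half the largest feature neighborhood so per-tile
    features match whole-image features on each tile's core columns.
    """
    overlap = max(model.feature_sizes) // 2
    tiles = slice_tiles(img, max_pixels=max_pixels, overlap_px=overlap)
    tmask = _tissue_pixels(tissue)
    out = np.zeros(img.shape, dtype=bool)
    for t in tiles.tiles:
        lo = t.col_offset
        hi = lo + t.image.shape[1]
        sub_tissue = BinaryMask(tmask[:, lo:hi])
        sub_mask = apply_cascade(model, t.image, sub_tissue)
        a = t.core_col_start - lo
        b = t.core_col_stop - lo
        out[:, t.core_col_start : t.core_col_stop] = sub_mask.pixels[:, a:b]
    return BinaryMask(out)


def save_model(path: str | Path, model: CascadeModel) -> None:
    """Serialize a trained cascade (layers, cost matrices, feature config, seed)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> CascadeModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, CascadeModel):
        raise ValueError(f"{path} does not contain a cascade model")
    return model
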