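"""Concentration regions and marker co-existence measures.

A *concentration region* is an automatically delimited area where a marker's
local density is high.  Per section, a characteristic radius R(M) is
estimated from the histogram of tissue-pixel distances to the nearest marker
pixel: R_MAX is the distance bin where that histogram peaks, R_LIMIT caps it
so that fewer than 50*A_M pixels lie within R_LIMIT of the markers, and
R = min(R_LIMIT, R_MAX).  Core regions are tissue pixels closer than R/2 to
a marker (small cores, area < 10*(R/2)^2, are dropped); surviving cores are
expanded to the connected components of the distance-< R mask containing
them, and expanded regions smaller than 20*R^2 are discarded.

Between two registered sections the following measures are computed
(A(x) = pixel count):

    DM_Ci    = A_Mi / CA_i              density of marker i in its own regions
    DM_1InC2 = A_{M1 ∩ Conc2} / CA_2    density of marker 1 in marker 2's regions
    PM_1InC2 = A_{M1 ∩ Conc2} / A_M1    fraction of marker 1 inside Conc2
    w        = min(DM_C1, DM_C2) / max(DM_C1, DM_C2)
    wMean_Dens = w * (DM_1InC2 + DM_2InC1) / 2
    wMean_AVG  = w * (PM_1InC2 + PM_2InC1) / 2

All measures can be restricted to a rectangular ROI, in which case tissue
densities use the ROI area (DM_Ti = A_Mi / ROIA).  Ratios with a zero
denominator are reported as NaN (undefined), never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .io import BinaryMask
from .quant import MarkerSegmentation
from .registration import RegisteredSet, gtro
from .tissue import TissueRegion

__all__ = [
    "RadiusEstimate",
    "ConcentrationRegionSet",
    "CoexistenceReport",
    "distance_map",
    "estimate_R",
    "concentration_regions",
    "coexistence_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RadiusEstimate:
    R: float
    R_MAX: float
    R_LIMIT: float
    distance_histogram: np.ndarray  # tissue-pixel counts per 1-px distance bin


@dataclass
class ConcentrationRegionSet:
    labels: np.ndarray  # 0 = background, 1..n = regions
    R_used: RadiusEstimate
    CA_per_region: dict[int, int]
    CA_total: int
    frame: str = "native"

    @property
    def n_regions(self) -> int:
        return len(self.CA_per_region)

    @property
    def mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, frame=self.frame)


def distance_map(tissue: TissueRegion | BinaryMask, seg: MarkerSegmentation) -> np.ndarray:
    """Per-tissue-pixel Euclidean distance to the nearest marker pixel.

    Marker pixels have distance 0; pixels outside the tissue are NaN and
    never participate in any downstream computation.
    """
    tmask = tissue.mask.pixels if isinstance(tissue, TissueRegion) else tissue.pixels
    if seg.A_M == 0:
        raise ValueError("empty marker mask: distance map undefined")
    if seg.M.shape != tmask.shape:
        raise ValueError("tissue and marker masks must share shape")
    dist = ndimage.distance_transform_edt(~seg.M.pixels)
    out = np.where(tmask, dist, np.nan)
    return out


def estimate_R(dmap: np.ndarray, A_M: int) -> RadiusEstimate:
    """Estimate the concentration radius R = min(R_LIMIT, R_MAX).

    The histogram of tissue distances uses 1-px bins [r, r+1); R_MAX is the
    center of the first maximal bin.  R_LIMIT is the largest integer r such
    that the number of tissue pixels at distance < r is below 50*A_M (when
    that cap never binds within the tissue, R_LIMIT exceeds every observed
    distance and R = R_MAX).  R is floored at 1 px.
    """
    if A_M <= 0:
        raise ValueError("A_M must be positive")
    d = dmap[np.isfinite(dmap)]
    if d.size == 0:
        raise ValueError("distance map has no tissue pixels")
    hist = np.bincount(np.floor(d).astype(np.int64))
    if d.max() == 0:
        logger.warning("all tissue pixels are marker pixels; R degenerates to 1 px")
        return RadiusEstimate(R=1.0, R_MAX=0.5, R_LIMIT=1.0, distance_histogram=hist)
    r_max = float(np.argmax(hist)) + 0.5  # first maximal bin, bin center

    cum = np.cumsum(hist)  # cum[k] = #pixels with distance < k+1
    cap = 50 * A_M
    # largest integer r with #(distance < r) < cap
    r_limit = 1.0
    for r in range(1, len(hist) + 1):
        if cum[r - 1] < cap:
            r_limit = float(r)
        else:
            break
    if cum[-1] < cap:  # cap never binds within the tissue
        r_limit = float(len(hist))
    R = max(1.0, min(r_limit, r_max))
    return RadiusEstimate(R=R, R_MAX=r_max, R_LIMIT=r_limit, distance_histogram=hist)


def concentration_regions(
    tissue: TissueRegion | BinaryMask,
    seg: MarkerSegmentation,
    R: RadiusEstimate | float | None = None,
) -> ConcentrationRegionSet:
    """Extract the section's concentration regions for one marker.

    Steps: (1) core = tissue pixels with distance < R/2 from any marker;
    (2) core components with area < 10*(R/2)^2 are deleted; (3) surviving
    cores are expanded to the connected components of the distance-< R mask
    that contain them; (4) expanded components with area < 20*R^2 are
    discarded.  An empty result is valid (section has no concentration
    region).
    """
    tmask = tissue.mask.pixels if isinstance(tissue, TissueRegion) else tissue.pixels
    frame = (tissue.mask.frame if isinstance(tissue, TissueRegion) else tissue.frame)
    empty = lambda Rv: ConcentrationRegionSet(
        labels=np.zeros(tmask.shape, dtype=np.int32),
        R_used=Rv,
        CA_per_region={},
        CA_total=0,
        frame=frame,
    )
    if seg.A_M == 0:
        return empty(RadiusEstimate(R=1.0, R_MAX=1.0, R_LIMIT=1.0, distance_histogram=np.array([0])))
    dmap = distance_map(BinaryMask(tmask, frame=frame), seg)
    if R is None:
        R = estimate_R(dmap, seg.A_M)
    elif not isinstance(R, RadiusEstimate):
        R = RadiusEstimate(R=float(R), R_MAX=float(R), R_LIMIT=float(R), distance_histogram=np.array([]))
    Rv = R.R

    with np.errstate(invalid="ignore"):
        core = np.isfinite(dmap) & (dmap < Rv / 2.0)
        near = np.isfinite(dmap) & (dmap < Rv)

    core_labels, n_core = measure.label(core, connectivity=2, return_num=True)
    if n_core:
        counts = np.bincount(core_labels.ravel())
        keep = counts >= 10.0 * (Rv / 2.0) ** 2
        keep[0] = False
        core = keep[core_labels]
    if not core.any():
        return empty(R)

    near_labels, n_near = measure.label(near, connectivity=2, return_num=True)
    touching = np.unique(near_labels[core])
    touching = touching[touching > 0]
    near_counts = np.bincount(near_labels.ravel())
    out = np.zeros(tmask.shape, dtype=np.int32)
    CA: dict[int, int] = {}
    next_label = 1
    for lab in touching:
        area = int(near_counts[lab])
        if area < 20.0 * Rv * Rv:
            continue
        out[near_labels == lab] = next_label
        CA[next_label] = area
        next_label += 1
    return ConcentrationRegionSet(
        labels=out, R_used=R, CA_per_region=CA, CA_total=int(sum(CA.values())), frame=frame
    )


def _ratio(num: int, denom: int) -> float:
    return num / denom if denom > 0 else math.nan


@dataclass
class CoexistenceReport:
    """All per-marker and pairwise co-existence measures of a registered set."""

    marker_names: list[str]
    per_marker: dict[str, dict[str, float]]  # DM_T, DM_C, A_M, CA
    per_pair: dict[tuple[str, str], dict[str, float]]
    GTRO: float
    ROIA: int | None = None

    def pair(self, a: str, b: str) -> dict[str, float]:
        if (a, b) in self.per_pair:
            return self.per_pair[(a, b)]
        # swap the directional fields for the reversed ordering
        p = self.per_pair[(b, a)]
        return {
            "DM_1InC2": p["DM_2InC1"],
            "DM_2InC1": p["DM_1InC2"],
            "PM_1InC2": p["PM_2InC1"],
            "PM_2InC1": p["PM_1InC2"],
            "w": p["w"],
            "wMean_Dens": p["wMean_Dens"],
            "wMean_AVG": p["wMean_AVG"],
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (a, b), p in self.per_pair.items():
            rows.append({"marker_1": a, "marker_2": b, **p})
        return pd.DataFrame(rows)

    def marker_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"marker": m, **vals} for m, vals in self.per_marker.items()]
        )


def _clip(mask: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    return mask if roi is None else (mask & roi)


def coexistence_report(
    registered: RegisteredSet,
    regions: list[ConcentrationRegionSet],
    roi: BinaryMask | tuple[int, int, int, int] | None = None,
    marker_names: list[str] | None = None,
) -> CoexistenceReport:
    """Compute every co-existence measure over a registered serial set.

    ``regions[i]`` must be the concentration regions of section i computed in
    the registered frame.  With an ROI (mask or (r0, c0, r1, c1) rectangle),
    markers and regions are clipped to it and tissue densities use ROIA.
    """
    n = len(registered.marker_masks)
    if len(regions) != n:
        raise ValueError("one ConcentrationRegionSet per section required")
    if marker_names is None:
        marker_names = [f"M{i + 1}" for i in range(n)]

    roi_mask: np.ndarray | None = None
    ROIA: int | None = None
    if roi is not None:
        if isinstance(roi, BinaryMask):
            roi_mask = roi.pixels
        else:
            r0, c0, r1, c1 = roi
            roi_mask = np.zeros(registered.shape, dtype=bool)
            roi_mask[r0:r1, c0:c1] = True
        ROIA = int(roi_mask.sum())
        if ROIA == 0:
            raise ValueError("empty ROI")

    markers, concs, CAs, A_Ms, tissue_areas = [], [], [], [], []
    for i in range(n):
        mk = registered.marker_masks[i]
        if mk is None:
            raise ValueError(f"section {i} has no marker mask")
        m = _clip(mk.pixels, roi_mask)
        conc = _clip(regions[i].labels > 0, roi_mask)
        markers.append(m)
        concs.append(conc)
        A_Ms.append(int(m.sum()))
        CAs.append(int(conc.sum()))
        denom = ROIA if ROIA is not None else registered.tissue_masks[i].area
        tissue_areas.append(denom)

    per_marker = {}
    DM_C = []
    for i, name in enumerate(marker_names):
        dmt = _ratio(A_Ms[i], tissue_areas[i])
        dmc = _ratio(A_Ms[i], CAs[i])
        DM_C.append(dmc)
        per_marker[name] = {"DM_T": dmt, "DM_C": dmc, "A_M": A_Ms[i], "CA": CAs[i]}

    per_pair = {}
    for i in range(n):
        for j in range(i + 1, n):
            a_in_cj = int((markers[i] & concs[j]).sum())
            b_in_ci = int((markers[j] & concs[i]).sum())
            dm_1in2 = _ratio(a_in_cj, CAs[j])
            dm_2in1 = _ratio(b_in_ci, CAs[i])
            pm_1in2 = _ratio(a_in_cj, A_Ms[i])
            pm_2in1 = _ratio(b_in_ci, A_Ms[j])
            if math.isnan(DM_C[i]) or math.isnan(DM_C[j]) or max(DM_C[i], DM_C[j]) == 0:
                w = math.nan
                logger.warning(
                    "pair (%s, %s): undefined concentration density; "
                    "weighted means reported as NaN", marker_names[i], marker_names[j],
                )
            else:
                w = min(DM_C[i], DM_C[j]) / max(DM_C[i], DM_C[j])
            per_pair[(marker_names[i], marker_names[j])] = {
                "DM_1InC2": dm_1in2,
                "DM_2InC1": dm_2in1,
                "PM_1InC2": pm_1in2,
                "PM_2InC1": pm_2in1,
                "w": w,
                "wMean_Dens": w * (dm_1in2 + dm_2in1) / 2.0,
                "wMean_AVG": w * (pm_1in2 + pm_2in1) / 2.0,
            }

    return CoexistenceReport(
        marker_names=marker_names,
        per_marker=per_marker,
        per_pair=per_pair,
        GTRO=gtro(registered.tissue_masks),
        ROIA=ROIA,
    )
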