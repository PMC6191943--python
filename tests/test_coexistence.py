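import math

import numpy as np
import pytest

import histoquant as hq
from histoquant.coexistence import (
    ConcentrationRegionSet,
    RadiusEstimate,
    coexistence_report,
    concentration_regions,
    distance_map,
    estimate_R,
)
from histoquant.io import BinaryMask
from histoquant.quant import MarkerSegmentation
from histoquant.registration import RegisteredSet, SimilarityTransform
from histoquant.synthetic import Cluster, MarkerLayout, SyntheticSpec
from histoquant.tissue import TissueRegion


def seg_of(mask: np.ndarray) -> MarkerSegmentation:
    return MarkerSegmentation.from_mask(BinaryMask(mask))


class TestDistanceMap:
    def test_three_four_five_triangle(self):
        tissue = BinaryMask(np.ones((10, 10), bool))
        mk = np.zeros((10, 10), bool)
        mk[0, 0] = True
        d = distance_map(tissue, seg_of(mk))
        assert d[3, 4] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_all_marker_all_zero(self):
        tissue = BinaryMask(np.ones((6, 6), bool))
        d = distance_map(tissue, seg_of(np.ones((6, 6), bool)))
        assert np.nanmax(d) == 0.0

    def test_outside_tissue_is_nan(self):
        tissue = np.zeros((6, 6), bool)
        tissue[2:4, 2:4] = True
        mk = np.zeros((6, 6), bool)
        mk[2, 2] = True
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        assert np.isnan(d[0, 0])
        assert np.isfinite(d[tissue]).all()

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        tissue = rng.random((32, 32)) < 0.8
        mk = (rng.random((32, 32)) < 0.05) & tissue
        if not mk.any():
            mk[10, 10] = True
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        mk_pts = np.argwhere(mk)
        for r, c in np.argwhere(tissue):
            brute = np.sqrt(((mk_pts - [r, c]) ** 2).sum(axis=1)).min()
            assert d[r, c] == pytest.approx(brute)

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError, match="empty marker"):
            distance_map(BinaryMask(np.ones((5, 5), bool)), seg_of(np.zeros((5, 5), bool)))


class TestEstimateR:
    def test_cap_binds_for_sparse_markers_in_huge_tissue(self):
        tissue = np.ones((200, 200), bool)
        mk = np.zeros((200, 200), bool)
        mk[100, 100] = mk[100, 101] = mk[101, 100] = True  # A_M = 3
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        est = estimate_R(d, 3)
        # manual R_LIMIT: largest r with #(distance < r) < 150
        vals = d[np.isfinite(d)]
        r_limit = max(r for r in range(1, 300) if (vals < r).sum() < 50 * 3)
        assert est.R_LIMIT == r_limit
        assert est.R == min(est.R_LIMIT, est.R_MAX)
        assert est.R == est.R_LIMIT  # peak is far out, cap must bind
        assert est.R_MAX > est.R_LIMIT

    def test_uniform_grid_peak_near_half_spacing(self):
        tissue = np.ones((120, 120), bool)
        mk = np.zeros((120, 120), bool)
        mk[::10, ::10] = True  # grid spacing d = 10
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        est = estimate_R(d, int(mk.sum()))
        assert 3.0 <= est.R_MAX <= 8.0  # ~d/2

    def test_cap_never_binds_when_markers_dense(self):
        tissue = np.ones((40, 40), bool)
        mk = np.zeros((40, 40), bool)
        mk[::2, ::2] = True  # A_M = 400 >= tissue/50
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        est = estimate_R(d, int(mk.sum()))
        assert est.R == est.R_MAX

    def test_degenerate_all_marker_floors_at_one(self):
        tissue = np.ones((8, 8), bool)
        d = distance_map(BinaryMask(tissue), seg_of(np.ones((8, 8), bool)))
        est = estimate_R(d, 64)
        assert est.R == 1.0

    def test_first_maximal_bin_wins_ties(self):
        # two pixels at distance 0 and two at distance 1: bins tie, first wins
        tissue = np.ones((1, 4), bool)
        mk = np.zeros((1, 4), bool)
        mk[0, 0] = mk[0, 2] = True
        d = distance_map(BinaryMask(tissue), seg_of(mk))
        est = estimate_R(d, 2)
        assert est.R_MAX == 0.5


class TestConcentrationRegions:
    def _clustered_section(self):
        layout = MarkerLayout(
            n_uniform=10,
            clusters=[Cluster(center=(200, 132), sd=9, count=40),
                      Cluster(center=(200, 268), sd=9, count=40)],
        )
        return hq.generate_section(
            SyntheticSpec(seed=42, height=400, width=400, markers=layout)
        )

    def test_two_planted_clusters_found(self):
        s = self._clustered_section()
        seg = seg_of(s.marker_mask.pixels)
        regions = concentration_regions(s.tissue_mask, seg)
        assert regions.n_regions == 2
        R = regions.R_used.R
        d = distance_map(s.tissue_mask, seg)
        for center in [(200, 132), (200, 268)]:
            lab = regions.labels[center]
            assert lab > 0
            # ground truth: the distance-<R envelope of that cluster's dots
            cluster = np.zeros_like(s.marker_mask.pixels)
            yy, xx = np.mgrid[0 : cluster.shape[0], 0 : cluster.shape[1]]
            near_center = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= (4 * 9 + R) ** 2
            with np.errstate(invalid="ignore"):
                envelope = near_center & np.nan_to_num(d, nan=np.inf).__lt__(R)
            got = regions.labels == lab
            iou = (got & envelope).sum() / (got | envelope).sum()
            assert iou >= 0.8

    def test_region_areas_respect_filter(self):
        s = self._clustered_section()
        regions = concentration_regions(s.tissue_mask, seg_of(s.marker_mask.pixels))
        R = regions.R_used.R
        for lab, area in regions.CA_per_region.items():
            assert area >= 20 * R * R
            assert ((regions.labels == lab) & s.marker_mask.pixels).any()

    def test_nesting_core_in_region_in_envelope(self):
        s = self._clustered_section()
        seg = seg_of(s.marker_mask.pixels)
        regions = concentration_regions(s.tissue_mask, seg)
        d = distance_map(s.tissue_mask, seg)
        with np.errstate(invalid="ignore"):
            envelope = np.isfinite(d) & (d < regions.R_used.R)
        assert not (regions.mask.pixels & ~envelope).any()

    def test_single_tiny_dot_yields_no_region(self):
        tissue = np.ones((100, 100), bool)
        mk = np.zeros((100, 100), bool)
        mk[50, 50] = mk[50, 51] = mk[51, 50] = True
        regions = concentration_regions(
            BinaryMask(tissue), seg_of(mk), R=RadiusEstimate(20.0, 20.0, 20.0, np.array([]))
        )
        # core is a disc of area ~pi*100 < 10*(R/2)^2 = 1000 -> filtered
        assert regions.n_regions == 0

    def test_empty_markers_empty_set(self):
        regions = concentration_regions(
            BinaryMask(np.ones((30, 30), bool)), seg_of(np.zeros((30, 30), bool))
        )
        assert regions.n_regions == 0
        assert regions.CA_total == 0


def manual_region_set(labels: np.ndarray) -> ConcentrationRegionSet:
    CA = {int(k): int((labels == k).sum()) for k in np.unique(labels) if k > 0}
    return ConcentrationRegionSet(
        labels=labels,
        R_used=RadiusEstimate(5.0, 5.0, 5.0, np.array([])),
        CA_per_region=CA,
        CA_total=int(sum(CA.values())),
        frame="registered",
    )


def manual_registered_set(tissues, markers):
    tm = [BinaryMask(t, frame="registered") for t in tissues]
    mm = [BinaryMask(m, frame="registered") for m in markers]
    return RegisteredSet(
        reference_index=0,
        transforms=[SimilarityTransform() for _ in tm],
        tissue_masks=tm,
        marker_masks=mm,
        GTRO_before=0.0,
        GTRO_after=0.0,
        shape=tm[0].shape,
    )


class TestCoexistenceReport:
    def test_identical_sections_coexist_fully(self):
        rng = np.random.default_rng(1)
        tissue = np.ones((40, 40), bool)
        mk = rng.random((40, 40)) < 0.1
        lab = np.zeros((40, 40), np.int32)
        lab[5:35, 5:35] = 1
        mk &= lab > 0
        regs = manual_registered_set([tissue, tissue], [mk, mk])
        report = coexistence_report(regs, [manual_region_set(lab)] * 2)
        p = report.pair("M1", "M2")
        assert p["PM_1InC2"] == 1.0 and p["PM_2InC1"] == 1.0
        assert p["w"] == 1.0
        assert p["wMean_AVG"] == pytest.approx(1.0)  # 100%

    def test_weight_from_concentration_densities(self):
        # DM_C1 = 698/10000 = 6.98%, DM_C2 = 944/10000 = 9.44%
        tissue = np.ones((200, 100), bool)
        lab = np.zeros((200, 100), np.int32)
        lab[0:100, :] = 1  # CA = 10000 for both sections
        m1 = np.zeros((200, 100), bool)
        m1.flat[:698] = True
        m2 = np.zeros((200, 100), bool)
        m2.flat[:944] = True
        regs = manual_registered_set([tissue, tissue], [m1, m2])
        report = coexistence_report(regs, [manual_region_set(lab)] * 2)
        assert report.per_marker["M1"]["DM_C"] == pytest.approx(0.0698)
        assert report.per_marker["M2"]["DM_C"] == pytest.approx(0.0944)
        assert report.pair("M1", "M2")["w"] == pytest.approx(6.98 / 9.44)

    def test_all_fields_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tissue = np.ones((48, 48), bool)
            m1 = rng.random((48, 48)) < 0.08
            m2 = rng.random((48, 48)) < 0.12
            lab1 = np.zeros((48, 48), np.int32)
            lab2 = np.zeros((48, 48), np.int32)
            lab1[4:30, 4:30] = 1
            lab2[20:45, 10:40] = 1
            regs = manual_registered_set([tissue, tissue], [m1, m2])
            report = coexistence_report(
                regs, [manual_region_set(lab1), manual_region_set(lab2)]
            )
            c1, c2 = lab1 > 0, lab2 > 0
            CA1, CA2 = c1.sum(), c2.sum()
            A1, A2 = m1.sum(), m2.sum()
            p = report.pair("M1", "M2")
            assert p["DM_1InC2"] == pytest.approx((m1 & c2).sum() / CA2, abs=1e-12)
            assert p["DM_2InC1"] == pytest.approx((m2 & c1).sum() / CA1, abs=1e-12)
            assert p["PM_1InC2"] == pytest.approx((m1 & c2).sum() / A1, abs=1e-12)
            assert p["PM_2InC1"] == pytest.approx((m2 & c1).sum() / A2, abs=1e-12)
            dc1, dc2 = A1 / CA1, A2 / CA2
            w = min(dc1, dc2) / max(dc1, dc2)
            assert p["w"] == pytest.approx(w, abs=1e-12)
            assert p["wMean_Dens"] == pytest.approx(
                w * (p["DM_1InC2"] + p["DM_2InC1"]) / 2, abs=1e-12
            )
            assert p["wMean_AVG"] == pytest.approx(
                w * (p["PM_1InC2"] + p["PM_2InC1"]) / 2, abs=1e-12
            )

    def test_symmetry_of_weighted_means(self):
        rng = np.random.default_rng(3)
        tissue = np.ones((30, 30), bool)
        m1 = rng.random((30, 30)) < 0.1
        m2 = rng.random((30, 30)) < 0.1
        lab = np.zeros((30, 30), np.int32)
        lab[5:25, 5:25] = 1
        regs = manual_registered_set([tissue, tissue], [m1, m2])
        report = coexistence_report(regs, [manual_region_set(lab)] * 2)
        a = report.pair("M1", "M2")
        b = report.pair("M2", "M1")
        assert a["wMean_AVG"] == b["wMean_AVG"]
        assert a["PM_1InC2"] == b["PM_2InC1"]

    def test_pm_monotone_in_added_overlap(self):
        tissue = np.ones((20, 20), bool)
        lab = np.zeros((20, 20), np.int32)
        lab[:10, :] = 1
        m2 = np.zeros((20, 20), bool)
        m2[2, 2] = m2[2, 3] = m2[3, 2] = True
        prev = -1.0
        m1 = np.zeros((20, 20), bool)
        m1[15, 15] = True  # starts outside Conc2
        for extra in range(5):
            m1[5, 5 + extra] = True  # add marker pixels inside Conc2
            regs = manual_registered_set([tissue, tissue], [m1, m2])
            report = coexistence_report(regs, [manual_region_set(lab)] * 2)
            pm = report.pair("M1", "M2")["PM_1InC2"]
            assert pm >= prev
            prev = pm

    def test_undefined_measures_are_nan_not_zero(self):
        tissue = np.ones((10, 10), bool)
        m1 = np.zeros((10, 10), bool)
        m1[1, 1] = True
        empty_lab = np.zeros((10, 10), np.int32)
        regs = manual_registered_set([tissue, tissue], [m1, m1])
        report = coexistence_report(regs, [manual_region_set(empty_lab)] * 2)
        p = report.pair("M1", "M2")
        assert math.isnan(p["DM_1InC2"])
        assert math.isnan(p["w"])

    def test_roi_restriction_uses_roia(self):
        rng = np.random.default_rng(4)
        tissue = np.ones((40, 40), bool)
        m1 = rng.random((40, 40)) < 0.2
        lab = np.zeros((40, 40), np.int32)
        lab[:, :] = 1
        regs = manual_registered_set([tissue, tissue], [m1, m1])
        report = coexistence_report(
            regs, [manual_region_set(lab)] * 2, roi=(0, 0, 20, 20)
        )
        assert report.ROIA == 400
        expected = m1[:20, :20].sum() / 400
        assert report.per_marker["M1"]["DM_T"] == pytest.approx(expected, abs=1e-12)
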