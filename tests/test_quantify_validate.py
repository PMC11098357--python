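"""ROI sampling, confusion metrics, FWHM profiles, density, diameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import erf

from vesselvol.quantify_validate import (
    EmptyGraphError,
    NoVesselError,
    RoiError,
    RoiSpec,
    compare_vessel_diameter,
    diameter_summary,
    profile_diameter,
    sample_rois,
    score_segmentation,
    select_path_nodes,
    validate_segmentation,
    vessel_density,
)
from vesselvol.volio import BinaryMask, SwcNode, VesselGraph


class TestSampleRois:
    def test_hundred_rois_in_bounds(self):
        rois = sample_rois((30, 500, 500), (5, 50, 50), n=100, seed=0)
        assert len(rois) == 100
        for roi in rois:
            roi.check_inside((30, 500, 500))

    def test_shape_equal_extent_forces_origin_zero(self):
        rois = sample_rois((5, 50, 50), (5, 50, 50), n=3, seed=0)
        assert [r.origin for r in rois] == [(0, 0, 0)] * 3

    def test_same_seed_same_rois(self):
        a = sample_rois((30, 200, 200), (5, 50, 50), n=20, seed=7)
        b = sample_rois((30, 200, 200), (5, 50, 50), n=20, seed=7)
        assert a == b

    def test_extent_larger_than_volume_rejected(self):
        with pytest.raises(RoiError):
            sample_rois((4, 50, 50), (5, 50, 50), n=1, seed=0)

    def test_reference_mask_rejects_empty_rois(self):
        vox = np.zeros((10, 100, 100), bool)
        vox[:, 40:60, 40:60] = True
        ref = BinaryMask(vox, (1, 1, 1))
        rois = sample_rois((10, 100, 100), (5, 20, 20), n=50, seed=3, reference=ref)
        assert all(ref.voxels[r.slices()].any() for r in rois)

    def test_vesselless_volume_exhausts_retry_budget(self):
        ref = BinaryMask(np.zeros((6, 20, 20), bool), (1, 1, 1))
        with pytest.raises(RoiError):
            sample_rois((6, 20, 20), (3, 5, 5), n=1, seed=0, reference=ref,
                        max_retries=50)


class TestScoreSegmentation:
    def test_identical_masks_score_perfectly(self, rng):
        m = rng.random((20, 20)) < 0.3
        s = score_segmentation(m, m)
        assert (s.sensitivity, s.specificity, s.dice) == (1.0, 1.0, 1.0)

    def test_empty_auto_vs_nonempty_manual(self):
        manual = np.zeros((4, 4), bool)
        manual[1:3, 1:3] = True
        s = score_segmentation(np.zeros((4, 4), bool), manual)
        assert s.sensitivity == 0.0 and s.dice == 0.0 and s.specificity == 1.0

    def test_hand_computed_confusion_counts(self):
        # tp=3, fp=1, fn=2, tn=10 on a 4x4 grid
        manual = np.zeros((4, 4), bool)
        manual.flat[[0, 1, 2, 3, 4]] = True          # 5 true pixels
        auto = np.zeros((4, 4), bool)
        auto.flat[[0, 1, 2, 5]] = True               # hits 3, misses 2, 1 false alarm
        s = score_segmentation(auto, manual)
        assert (s.tp, s.fp, s.fn, s.tn) == (3, 1, 2, 10)
        assert s.sensitivity == pytest.approx(0.6)
        assert s.specificity == pytest.approx(10 / 11)
        assert s.dice == pytest.approx(6 / 9)

    def test_degenerate_denominators_are_nan(self):
        s = score_segmentation(np.zeros((2, 2), bool), np.zeros((2, 2), bool))
        assert math.isnan(s.sensitivity) and math.isnan(s.dice)
        s2 = score_segmentation(np.ones((2, 2), bool), np.ones((2, 2), bool))
        assert math.isnan(s2.specificity)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_segmentation(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        auto=hnp.arrays(bool, (6, 6), elements=st.booleans()),
        manual=hnp.arrays(bool, (6, 6), elements=st.booleans()),
    )
    def test_complement_swap_and_dice_identity(self, auto, manual):
        s = score_segmentation(auto, manual)
        sc = score_segmentation(~auto, ~manual)
        # complementing both masks swaps sensitivity <-> specificity
        if not math.isnan(s.sensitivity):
            assert sc.specificity == pytest.approx(s.sensitivity)
        if not math.isnan(s.specificity):
            assert sc.sensitivity == pytest.approx(s.specificity)
        # dice * (2tp + fp + fn) == 2tp, and 0 <= dice <= 1
        if not math.isnan(s.dice):
            assert 0.0 <= s.dice <= 1.0
            assert s.dice * (2 * s.tp + s.fp + s.fn) == pytest.approx(2 * s.tp)
            assert (s.dice == 1.0) == np.array_equal(auto, manual) or auto.any()


class TestValidateSegmentation:
    def test_identical_masks_summary_is_one_pm_zero(self, rng):
        vox = rng.random((10, 80, 80)) < 0.2
        mask = BinaryMask(vox, (1, 1, 1))
        rois = sample_rois(mask.shape, (5, 20, 20), n=30, seed=1, reference=mask)
        table, summary = validate_segmentation(mask, mask, rois)
        for metric in ("sensitivity", "specificity", "dice"):
            mean, sd = summary[metric]
            assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_summary_matches_recomputation_from_table(self, rng):
        truth = BinaryMask(rng.random((10, 80, 80)) < 0.15, (1, 1, 1))
        noisy = BinaryMask(
            truth.voxels ^ (rng.random((10, 80, 80)) < 0.05), (1, 1, 1)
        )
        rois = sample_rois(truth.shape, (5, 20, 20), n=40, seed=2, reference=truth)
        table, summary = validate_segmentation(noisy, truth, rois)
        assert len(table) == 40
        for metric in ("sensitivity", "specificity", "dice"):
            col = table[metric].dropna()
            assert summary[metric][0] == pytest.approx(col.mean())
            assert summary[metric][1] == pytest.approx(col.std(ddof=1))

    def test_single_roi_reports_sd_zero(self, rng):
        mask = BinaryMask(rng.random((6, 60, 60)) < 0.2, (1, 1, 1))
        _table, summary = validate_segmentation(
            mask, mask, [RoiSpec((0, 0, 0), (5, 50, 50))]
        )
        assert summary["dice"] == (pytest.approx(1.0), 0.0)

    def test_mip_and_3d_modes_differ_on_depth_structure(self):
        # auto misses one slice entirely; the z-MIP hides that, 3D does not
        manual = np.zeros((2, 8, 8), bool)
        manual[:, 2:6, 2:6] = True
        auto = manual.copy()
        auto[1] = False
        a, m = BinaryMask(auto, (1, 1, 1)), BinaryMask(manual, (1, 1, 1))
        roi = [RoiSpec((0, 0, 0), (2, 8, 8))]
        _t, mip_summary = validate_segmentation(a, m, roi, mode="mip")
        _t, vox_summary = validate_segmentation(a, m, roi, mode="3d")
        assert mip_summary["sensitivity"][0] == pytest.approx(1.0)
        assert vox_summary["sensitivity"][0] == pytest.approx(0.5)


class TestProfileDiameter:
    def test_top_hat_fwhm_is_its_width(self):
        img = np.zeros((21, 41))
        w = 7
        img[:, 17:17 + w] = 120.0
        d = profile_diameter(img, (10, 20), (0, 1), pixel_size=2.0, background=0.0)
        assert d == pytest.approx(w * 2.0, abs=0.02)

    def test_gaussian_blurred_profile_matches_quadrature_oracle(self):
        # cross-section of a width-2a tube blurred by a Gaussian of sd σ:
        # I(x) = A/2 [erf((x+a)/σ√2) − erf((x−a)/σ√2)], evaluated exactly
        a, sigma, amp, px = 3.0, 2.5, 100.0, 1.0
        x = np.arange(61.0) - 30.0

        def analytic(u):
            return amp / 2 * (erf((u + a) / (sigma * np.sqrt(2)))
                              - erf((u - a) / (sigma * np.sqrt(2))))

        img = np.tile(analytic(x), (21, 1))
        # dense numeric oracle on the analytic profile
        fine = np.linspace(-30, 30, 600001)
        prof = analytic(fine)
        half = prof.max() / 2
        above = prof >= half
        oracle_fwhm = fine[above][-1] - fine[above][0]
        d = profile_diameter(img, (10, 30), (0, 1), pixel_size=px, background=0.0)
        assert d == pytest.approx(oracle_fwhm, abs=0.1)

    def test_background_point_raises(self):
        img = np.zeros((21, 41))
        img[:, 30:33] = 100.0
        with pytest.raises(NoVesselError):
            profile_diameter(img, (10, 5), (0, 1), pixel_size=1.0, background=0.0)

    def test_diagonal_direction_measures_oblique_width(self):
        # 45° stripe: perpendicular width is w/√2 of the horizontal cut
        img = np.zeros((80, 80))
        ii, jj = np.mgrid[0:80, 0:80]
        img[np.abs(ii - jj) <= 5] = 50.0  # horizontal cut 11 px wide
        d = profile_diameter(
            img, (40, 40), (1 / np.sqrt(2), -1 / np.sqrt(2)), pixel_size=1.0,
            background=0.0,
        )
        assert d == pytest.approx(11 / np.sqrt(2), abs=0.5)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            profile_diameter(np.ones((5, 5)), (2, 2), (0, 0), pixel_size=1.0)


class TestCompareVesselDiameter:
    def test_absolute_difference_of_means(self):
        c = compare_vessel_diameter([2, 2, 2, 2, 2], [3, 3, 3, 3, 3])
        assert c.abs_difference == pytest.approx(1.0)
        assert compare_vessel_diameter([1.5] * 5, [1.5] * 5).abs_difference == 0.0
        c3 = compare_vessel_diameter(
            [1.8, 2.0, 2.2, 2.0, 2.0], [2.5, 2.4, 2.6, 2.5, 2.5]
        )
        assert c3.manual_mean == pytest.approx(2.0)
        assert c3.traced_mean == pytest.approx(2.5)
        assert c3.abs_difference == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "manual,traced",
        [([1, 2, 3], [1, 2, 3, 4, 5]), ([1] * 5, [1] * 6), ([1, 2, 3, 4, -5], [1] * 5)],
    )
    def test_wrong_count_or_nonpositive_rejected(self, manual, traced):
        with pytest.raises(ValueError):
            compare_vessel_diameter(manual, traced)


class TestVesselDensity:
    def test_extreme_masks(self):
        empty = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        full = BinaryMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        assert vessel_density(empty) == 0.0
        assert vessel_density(full) == 1.0

    def test_half_filled_block(self):
        vox = np.zeros((2, 2, 2), bool)
        vox[0] = True
        assert vessel_density(BinaryMask(vox, (1, 1, 1))) == pytest.approx(0.5)

    def test_region_restriction(self):
        vox = np.zeros((4, 4, 4), bool)
        vox[:2] = True
        mask = BinaryMask(vox, (1, 1, 1))
        assert vessel_density(mask, RoiSpec((0, 0, 0), (2, 4, 4))) == 1.0
        assert vessel_density(mask, RoiSpec((2, 0, 0), (2, 4, 4))) == 0.0

    def test_cylinder_density_matches_analytic_volume(self, straight_tube_phantom):
        spec, (_stack, truth, _graph) = straight_tube_phantom
        r = float(np.asarray(spec.tubes[0].radius)[0])
        length = 40.0  # tube spans the full x extent (voxel centers 0..39, +edges)
        analytic = math.pi * r * r * length / np.prod(truth.shape)
        assert vessel_density(truth) == pytest.approx(analytic, rel=0.1)


class TestDiameterSummary:
    def test_uniform_radii(self):
        g = VesselGraph([SwcNode(i, float(i), 0, 0, 1.5) for i in range(1, 4)])
        table, stats = diameter_summary(g)
        assert stats["mean"] == pytest.approx(3.0) and stats["sd"] == 0.0
        assert list(table["diameter"]) == [3.0, 3.0, 3.0]

    def test_two_node_stats(self):
        g = VesselGraph([SwcNode(1, 0, 0, 0, 1.0), SwcNode(2, 1, 0, 0, 2.0)])
        _t, stats = diameter_summary(g)
        assert (stats["min"], stats["max"], stats["mean"]) == (2.0, 4.0, 3.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(EmptyGraphError):
            diameter_summary(VesselGraph([]))


class TestSelectPathNodes:
    def test_selects_interior_equally_spaced_nodes(self):
        # straight chain of 13 nodes, 1 μm apart
        nodes = [SwcNode(i, float(i - 1), 0, 0, 1.0, parent=i - 1 if i > 1 else -1)
                 for i in range(1, 14)]
        g = VesselGraph(nodes)
        chosen = select_path_nodes(g, n=5)
        assert len(chosen) == 5
        xs = sorted(n.x for n in chosen)
        assert xs == pytest.approx([2.0, 4.0, 6.0, 8.0, 10.0])
        assert 0.0 not in xs and 12.0 not in xs  # endpoints excluded
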