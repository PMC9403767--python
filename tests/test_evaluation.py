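"""Dice, surface distance, site matching, sensitivity and false-positive metrics."""

import itertools

import numpy as np
import pytest

from hepaseg import (dice, equivalent_diameter, evaluate_cohort, evaluate_patient,
                     false_positive_metrics, generate_phantom, global_dice,
                     label_components, match_sites, median_surface_distance,
                     random_phantom_spec, site_sensitivity)
from hepaseg.errors import AlignmentError
from hepaseg.volumes import BinaryMask, CTVolume


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(arr).astype(np.uint8), spacing)


def _box(shape, sl, spacing=(1.0, 1.0, 1.0)):
    arr = np.zeros(shape)
    arr[sl] = 1
    return _mask(arr, spacing)


class TestDice:
    def test_identical_masks(self):
        m = _box((6, 6, 6), np.s_[1:4, 1:4, 1:4])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _box((6, 6, 6), np.s_[0:2, 0:2, 0:2])
        b = _box((6, 6, 6), np.s_[4:6, 4:6, 4:6])
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = _box((4, 4, 4), np.s_[0:2, 0:2, 0:2])   # 8 voxels
        b = _box((4, 4, 4), np.s_[1:3, 0:2, 0:2])   # 8 voxels, 4 shared
        assert dice(a, b) == 0.5

    def test_empty_conventions(self):
        e = _mask(np.zeros((3, 3, 3)))
        m = _box((3, 3, 3), np.s_[0:1, 0:1, 0:1])
        assert dice(e, e) == 1.0
        assert dice(e, m) == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = _mask(rng.random((8, 8, 8)) < 0.3)
            b = _mask(rng.random((8, 8, 8)) < 0.3)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_grid_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4)))
        b = BinaryMask(np.ones((4, 4, 4), np.uint8), (2.0, 1.0, 1.0))
        with pytest.raises(AlignmentError):
            dice(a, b)


class TestGlobalDice:
    def test_stacking_differs_from_averaging(self):
        """Pooled DSC weights patients by size: {8,8,∩4} + {2,2,∩0} -> 0.4 vs mean 0.25."""
        a1 = _box((4, 4, 4), np.s_[0:2, 0:2, 0:2])
        b1 = _box((4, 4, 4), np.s_[1:3, 0:2, 0:2])
        a2 = _box((4, 4, 4), np.s_[0:1, 0:1, 0:2])
        b2 = _box((4, 4, 4), np.s_[3:4, 3:4, 0:2])
        pairs = [(a1, b1), (a2, b2)]
        assert global_dice(pairs) == pytest.approx(0.4)
        assert np.mean([dice(*p) for p in pairs]) == pytest.approx(0.25)

    def test_single_patient_equals_dice(self):
        a = _box((5, 5, 5), np.s_[1:3, 1:3, 1:3])
        b = _box((5, 5, 5), np.s_[1:3, 1:4, 1:3])
        assert global_dice([(a, b)]) == dice(a, b)

    def test_all_empty_is_one(self):
        e = _mask(np.zeros((3, 3, 3)))
        assert global_dice([(e, e), (e, e)]) == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            global_dice([])

    def test_matches_stacked_array_brute_force(self):
        rng = np.random.default_rng(1)
        pairs = []
        stacked_a, stacked_b = [], []
        for _ in range(5):
            a = rng.random((6, 6, 6)) < 0.3
            b = rng.random((6, 6, 6)) < 0.3
            pairs.append((_mask(a), _mask(b)))
            stacked_a.append(a)
            stacked_b.append(b)
        sa, sb = np.concatenate(stacked_a), np.concatenate(stacked_b)
        want = 2 * (sa & sb).sum() / (sa.sum() + sb.sum())
        assert global_dice(pairs) == pytest.approx(want)


def brute_force_msd(a, b, spacing):
    """Exhaustive pairwise-distance oracle over face-boundary voxels."""
    def surface(m):
        pts = []
        m = m.astype(bool)
        for p in np.argwhere(m):
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                q = p + d
                if np.any(q < 0) or np.any(q >= m.shape) or not m[tuple(q)]:
                    pts.append(p)
                    break
        return np.array(pts) * np.asarray(spacing)

    pa, pb = surface(a), surface(b)
    d_ab = [min(np.linalg.norm(x - y) for y in pb) for x in pa]
    d_ba = [min(np.linalg.norm(x - y) for y in pa) for x in pb]
    return float(np.median(d_ab + d_ba))


class TestSurfaceDistance:
    def test_identical_masks_zero(self):
        m = _box((6, 6, 6), np.s_[1:4, 1:4, 1:4])
        assert median_surface_distance(m, m) == 0.0

    def test_parallel_plates_unit_spacing(self):
        a = _box((8, 5, 5), np.s_[1:2, :, :])
        b = _box((8, 5, 5), np.s_[4:5, :, :])   # offset 3 voxels at 1 mm
        assert median_surface_distance(a, b) == pytest.approx(3.0)

    def test_parallel_plates_thick_slices(self):
        sp = (2.5, 1.0, 1.0)
        a = _box((8, 5, 5), np.s_[1:2, :, :], sp)
        b = _box((8, 5, 5), np.s_[3:4, :, :], sp)   # 2 slices at 2.5 mm
        assert median_surface_distance(a, b) == pytest.approx(5.0)

    def test_empty_mask_undefined(self):
        m = _box((4, 4, 4), np.s_[1:2, 1:2, 1:2])
        with pytest.raises(ValueError):
            median_surface_distance(m, _mask(np.zeros((4, 4, 4))))

    def test_translation_invariance(self):
        a = _box((10, 10, 10), np.s_[1:3, 1:4, 1:3])
        b = _box((10, 10, 10), np.s_[2:4, 1:4, 2:5])
        a2 = _box((10, 10, 10), np.s_[4:6, 4:7, 4:6])
        b2 = _box((10, 10, 10), np.s_[5:7, 4:7, 5:8])
        assert median_surface_distance(a, b) == pytest.approx(
            median_surface_distance(a2, b2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        """Random blob pairs (5 spacings x 10 seeds) agree with the O(n^2) oracle."""
        rng = np.random.default_rng(seed)
        for spacing in [(1, 1, 1), (2.5, 0.75, 0.75), (2, 1, 1), (1, 2, 3), (0.5, 0.5, 2)]:
            a = np.zeros((8, 8, 8))
            b = np.zeros((8, 8, 8))
            a[tuple(rng.integers(0, 6, 3))] = 1
            a = np.maximum(a, rng.random((8, 8, 8)) < 0.1)
            b = np.maximum(np.zeros((8, 8, 8)), rng.random((8, 8, 8)) < 0.1)
            if not a.any() or not b.any():
                continue
            got = median_surface_distance(_mask(a, spacing), _mask(b, spacing))
            assert got == pytest.approx(brute_force_msd(a, b, spacing))


class TestMatching:
    def test_nearest_centroid_wins(self):
        gt = np.zeros((20, 20, 20))
        gt[9:12, 9:12, 9:12] = 1           # centroid ~(10.5, 10.5, 10.5) mm
        pred = np.zeros((20, 20, 20))
        pred[9:12, 9:12, 11:14] = 1        # ~2 mm away
        pred[1:3, 1:3, 1:3] = 1            # far corner
        m = match_sites(label_components(_mask(gt)), label_components(_mask(pred)))
        pred_comps = label_components(_mask(pred))
        gt_comps = label_components(_mask(gt))
        (gid, pid), = m
        d = np.linalg.norm(pred_comps.centroids_mm[pid - 1] - gt_comps.centroids_mm[0])
        assert d < 3.0

    def test_no_predictions_unmatched(self):
        gt = label_components(_box((6, 6, 6), np.s_[1:3, 1:3, 1:3]))
        pred = label_components(_mask(np.zeros((6, 6, 6))))
        assert match_sites(gt, pred) == [(1, None)]

    def test_one_prediction_can_serve_two_sites(self):
        gt = np.zeros((6, 20, 6))
        gt[2:4, 1:3, 2:4] = 1
        gt[2:4, 16:18, 2:4] = 1
        pred = _box((6, 20, 6), np.s_[2:4, 8:12, 2:4])
        m = match_sites(label_components(_mask(gt)), label_components(pred))
        assert [pid for _, pid in m] == [1, 1]


class TestSensitivity:
    def test_boundary_inclusive_at_45_percent(self):
        gt = np.zeros((4, 10, 10))
        gt[1, :, :] = 1                      # 100 voxels
        pred = np.zeros((4, 10, 10))
        pred[1, :5, :9] = 1                  # 45 covered
        frac, det = site_sensitivity(gt, pred)
        assert frac == pytest.approx(0.45)
        assert det is True

    def test_just_below_boundary(self):
        gt = np.zeros((4, 10, 10))
        gt[1, :, :] = 1
        pred = np.zeros((4, 10, 10))
        pred[1, :4, :] = 1
        pred[1, 4, :4] = 1                   # 44 covered
        frac, det = site_sensitivity(gt, pred)
        assert frac == pytest.approx(0.44)
        assert det is False

    def test_full_coverage(self):
        gt = np.zeros((3, 3, 3))
        gt[1, 1, 1] = 1
        frac, det = site_sensitivity(gt, np.ones((3, 3, 3)))
        assert (frac, det) == (1.0, True)

    def test_fraction_classification_boundary(self):
        gt = np.zeros((1, 1, 10000))
        gt[0, 0, :] = 1
        pred = np.zeros_like(gt)
        pred[0, 0, :4500] = 1
        assert site_sensitivity(gt, pred)[1] is True
        pred[0, 0, 4499] = 0                  # 4499/10000 = 0.4499
        assert site_sensitivity(gt, pred)[1] is False

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            site_sensitivity(np.zeros((2, 2, 2)), np.ones((2, 2, 2)))


class TestFalsePositives:
    def test_hand_counted_example(self):
        """GT 100 voxels; overlapping pred +10 spill; disjoint pred 20 voxels."""
        gt = np.zeros((10, 20, 20))
        gt[2:6, 2:7, 2:7] = 1                       # 100 voxels
        pred = np.zeros((10, 20, 20))
        pred[2:6, 2:7, 2:7] = 1
        pred[2:6, 7, 2:7] = 0                       # keep A = GT...
        pred[6, 2:7, 2:4] = 1                       # ...plus 10 extra voxels
        pred[8, 12:17, 12:16] = 1                   # component B: 20 disjoint voxels
        disc, fp, err, over = false_positive_metrics(_mask(gt), _mask(pred))
        assert disc == 1
        assert fp == pytest.approx(0.030)
        assert err == pytest.approx(0.020)
        assert over == pytest.approx(0.010)

    def test_pred_subset_of_gt_all_zero(self):
        gt = _box((6, 6, 6), np.s_[1:5, 1:5, 1:5])
        pred = _box((6, 6, 6), np.s_[2:4, 2:4, 2:4])
        assert false_positive_metrics(gt, pred) == (0, 0.0, 0.0, 0.0)

    def test_exact_match_all_zero(self):
        gt = _box((6, 6, 6), np.s_[1:5, 1:5, 1:5])
        disc, fp, err, over = false_positive_metrics(gt, gt)
        assert (disc, fp) == (0, 0.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_conservation_on_random_pairs(self, seed):
        """erroneous + over-segmentation = total FP volume, to 1e-9 cc."""
        rng = np.random.default_rng(seed)
        gt = _mask(rng.random((10, 10, 10)) < 0.2, (2.0, 0.7, 0.7))
        pred = _mask(rng.random((10, 10, 10)) < 0.2, (2.0, 0.7, 0.7))
        _, fp, err, over = false_positive_metrics(gt, pred)
        assert err + over == pytest.approx(fp, abs=1e-9)
        assert fp >= 0 and err >= 0 and over >= 0


class TestDiameter:
    def test_closed_forms(self):
        assert equivalent_diameter(1.0) == pytest.approx(12.407, abs=0.01)
        assert equivalent_diameter(0.001) == pytest.approx(1.2407, abs=0.001)

    def test_rasterized_sphere(self):
        spec = random_phantom_spec(3, n_lesions=1, diameter_range_mm=(20.0, 20.0),
                                   shape=(40, 96, 96), spacing=(2.0, 1.0, 1.0))
        _, _, disease = generate_phantom(spec)
        comps = label_components(disease)
        assert equivalent_diameter(float(comps.volumes_cc[0])) == pytest.approx(20.0,
                                                                                rel=0.05)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)


class TestCohort:
    def test_perfect_case(self):
        gt = _box((8, 12, 12), np.s_[2:5, 3:7, 3:7])
        res = evaluate_cohort([(gt, gt, None)])
        p = res.patients[0]
        assert p.dsc == 1.0
        assert res.global_dsc == 1.0
        assert p.false_positive_discoveries == 0
        assert all(s.detected for s in p.site_results)

    def test_planted_sensitivity_fraction(self):
        """Sensitivity equals planted detected/total exactly."""
        gt = np.zeros((10, 30, 10))
        gt[2:5, 1:4, 2:5] = 1      # detected site
        gt[2:5, 10:13, 2:5] = 1    # missed site
        gt[2:5, 20:23, 2:5] = 1    # detected site
        pred = np.zeros((10, 30, 10))
        pred[2:5, 1:4, 2:5] = 1
        pred[2:5, 20:23, 2:5] = 1
        res = evaluate_cohort([(_mask(gt), _mask(pred), None)])
        assert res.size_summary["sensitivity"].iloc[0] == pytest.approx(2 / 3)

    def test_default_diameter_bins(self):
        gt = np.zeros((20, 64, 64))
        gt[4:15, 10:34, 10:34] = 1      # >= 15 mm equivalent
        gt[8:10, 40:44, 40:44] = 1      # small site
        m = _mask(gt, (2.5, 0.75, 0.75))
        res = evaluate_cohort([(m, m, None)])
        assert set(res.site_table["bin"]) == {"<15 mm", ">=15 mm"}

    def test_prediction_resampled_to_original_grid(self):
        gt = _box((8, 16, 16), np.s_[2:6, 4:12, 4:12], (2.0, 1.5, 1.5))
        # prediction on a finer grid covering the same physical region
        pred_fine = _box((16, 24, 24), np.s_[4:12, 6:18, 6:18], (1.0, 1.0, 1.0))
        orig = CTVolume(np.zeros((8, 16, 16), np.float32), (2.0, 1.5, 1.5))
        res = evaluate_cohort([(gt, pred_fine, orig)])
        assert res.patients[0].dsc == pytest.approx(1.0)

    def test_unmatched_site_scores_zero_dsc_and_missing_msd(self):
        gt = _box((6, 6, 6), np.s_[1:4, 1:4, 1:4])
        pred = _mask(np.zeros((6, 6, 6)))
        p = evaluate_patient(gt, pred)
        (s,) = p.site_results
        assert s.dsc == 0.0
        assert s.median_surface_distance_mm is None
        assert s.detected is False
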