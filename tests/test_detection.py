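"""Spot segmentation: binarization semantics, labeling, the volume filter,
threshold selection, and recovery of known synthetic ground truth."""

import numpy as np
import pytest
from _oracles import flood_fill_count

from smfish3d import (
    DetectionConfig,
    ImageStack,
    ThresholdCurve,
    binarize,
    detect_spots,
    evaluate_detection,
    filter_and_measure,
    label_components,
    scan_thresholds,
    select_threshold,
)
from smfish3d.errors import DegenerateInputError, FormatError


def _stack(arr):
    return ImageStack(np.asarray(arr))


class TestBinarize:
    def test_threshold_at_max_gives_empty_mask(self):
        stack = _stack(np.arange(8).reshape(2, 2, 2))
        assert not binarize(stack, 7).any()

    def test_strictly_greater_than_semantics(self):
        vox = np.zeros((1, 3, 3))
        vox[0, 1, 1] = 50
        mask = binarize(_stack(vox), 49.5)
        assert mask.sum() == 1 and mask[0, 1, 1]
        # a voxel exactly at the threshold is background
        assert binarize(_stack(vox), 50).sum() == 0

    def test_threshold_below_min_gives_all_foreground(self):
        stack = _stack(np.full((2, 2, 2), 5.0))
        assert binarize(stack, 4).all()


class TestLabelComponents:
    def test_diagonal_voxels_depend_on_connectivity(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        _, n26 = label_components(mask, connectivity=26)
        _, n6 = label_components(mask, connectivity=6)
        assert n26 == 1
        assert n6 == 2

    def test_empty_mask_has_zero_components(self):
        _, n = label_components(np.zeros((3, 3, 3), dtype=bool), 26)
        assert n == 0

    def test_disjoint_blocks_each_get_a_label(self):
        mask = np.zeros((4, 20, 4), dtype=bool)
        for k in range(10):
            mask[1:3, 2 * k : 2 * k + 1, 1:3] = True  # blocks separated by a gap
        mask[:, 1::2, :] = False
        _, n = label_components(mask, 26)
        assert n == flood_fill_count(mask, 26) == 10

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_on_random_masks(self, connectivity, rng):
        for _ in range(25):
            mask = rng.random((8, 8, 8)) < 0.25
            _, n = label_components(mask, connectivity)
            assert n == flood_fill_count(mask, connectivity)


class TestFilterAndMeasure:
    def test_single_voxel_specks_removed(self):
        vox = np.zeros((3, 9, 3))
        for k in range(3):
            vox[1, 3 * k + 1, 1] = 10  # isolated single voxels
        labeled, n = label_components(binarize(_stack(vox), 0), 26)
        assert n == 3
        spots = filter_and_measure(labeled, _stack(vox), DetectionConfig(min_volume=2))
        assert len(spots) == 0

    def test_cube_measured_at_its_center(self):
        vox = np.zeros((7, 7, 7))
        vox[2:5, 2:5, 2:5] = 10.0
        labeled, _ = label_components(binarize(_stack(vox), 0), 26)
        spots = filter_and_measure(labeled, _stack(vox), DetectionConfig())
        assert len(spots) == 1
        spot = spots.spots[0]
        assert spot.volume == 27
        assert spot.centroid == pytest.approx((3.0, 3.0, 3.0))
        assert spot.total_intensity == pytest.approx(270.0)
        assert spot.max_intensity == pytest.approx(10.0)

    def test_labels_renumbered_consecutively(self):
        vox = np.zeros((3, 12, 3))
        vox[1, 1, 1] = 5  # volume 1: filtered out
        vox[1, 4:6, 1] = 5  # volume 2: kept
        vox[1, 8:11, 1] = 5  # volume 3: kept
        labeled, _ = label_components(binarize(_stack(vox), 0), 26)
        spots = filter_and_measure(labeled, _stack(vox), DetectionConfig())
        assert spots.labels == [1, 2]

    def test_lowering_max_volume_never_adds_spots(self, small_scene):
        stack = small_scene.stack_a
        labeled, _ = label_components(binarize(stack, 100), 26)
        counts = [
            len(filter_and_measure(labeled, stack, DetectionConfig(max_volume=m)))
            for m in (200, 100, 40, 10, 2)
        ]
        assert counts == sorted(counts, reverse=True)


class TestThresholdCurve:
    def test_single_block_counts_one_everywhere(self):
        vox = np.zeros((9, 9, 9))
        vox[3:6, 3:6, 3:6] = 100.0
        curve = scan_thresholds(_stack(vox), DetectionConfig(max_volume=200))
        assert (curve.counts == 1).all()

    def test_constant_stack_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            scan_thresholds(_stack(np.full((3, 3, 3), 7.0)))

    def test_levels_strictly_interior_and_ascending(self, small_scene):
        curve = scan_thresholds(small_scene.stack_a)
        vox = small_scene.stack_a.voxels
        assert (np.diff(curve.thresholds) > 0).all()
        assert curve.thresholds[0] > vox.min()
        assert curve.thresholds[-1] < vox.max()

    def test_invalid_curves_rejected(self):
        with pytest.raises(FormatError):
            ThresholdCurve(thresholds=[3.0, 2.0, 1.0], counts=[1, 1, 1])
        with pytest.raises(FormatError):
            ThresholdCurve(thresholds=[1.0, 2.0], counts=[1, -1])


class TestSelectThreshold:
    def test_linear_counts_pick_lowest_eligible_level(self):
        thresholds = np.linspace(1, 100, 50)
        counts = np.linspace(500, 10, 50).astype(int)
        curve = ThresholdCurve(thresholds=thresholds, counts=counts)
        t = select_threshold(curve)
        # all slopes tie, so the tie-break lands on the first interior level
        edge = int(np.ceil(0.05 * 50))
        assert t == pytest.approx(thresholds[edge])
        assert curve.flat_warning

    def test_too_few_levels_rejected(self):
        curve = ThresholdCurve(thresholds=np.arange(5.0), counts=np.ones(5, dtype=int))
        with pytest.raises(DegenerateInputError):
            select_threshold(curve)

    def test_selected_threshold_recovers_true_count(self, small_scene):
        # oracle: exhaustive slope minimization on the recorded falling branch
        curve = scan_thresholds(small_scene.stack_a)
        t = select_threshold(curve)
        assert curve.counts[curve.selected_index] == small_scene.params.n_spots
        smoothed = np.convolve(curve.counts, np.ones(5) / 5, mode="same")
        grad = np.abs(np.gradient(smoothed, curve.thresholds))
        peak = int(np.argmax(smoothed))
        interior = np.arange(max(5, peak), len(grad) - 5)
        assert grad[curve.selected_index] <= grad[interior].min() + 1e-9
        assert small_scene.stack_a.voxels.min() < t < small_scene.stack_a.voxels.max()


class TestDetectSpots:
    def test_detection_is_deterministic(self, small_scene):
        s1 = detect_spots(small_scene.stack_a)
        s2 = detect_spots(small_scene.stack_a)
        assert s1.threshold_used == s2.threshold_used
        np.testing.assert_array_equal(s1.centroids, s2.centroids)
        assert [s.volume for s in s1.spots] == [s.volume for s in s2.spots]

    def test_manual_threshold_equals_direct_binarization_path(self, small_scene):
        auto = detect_spots(small_scene.stack_a)
        manual = detect_spots(
            small_scene.stack_a,
            DetectionConfig(manual_threshold=auto.threshold_used),
        )
        np.testing.assert_array_equal(auto.centroids, manual.centroids)
        assert manual.curve is None

    def test_noise_only_scene_yields_no_spots(self):
        from smfish3d import SceneParams, simulate_scene

        for seed in range(10):
            scene = simulate_scene(
                SceneParams(shape=(8, 80, 80), n_spots=0, n_nuclei=0, seed=seed)
            )
            spots = detect_spots(scene.stack_a)
            assert len(spots) == 0

    def test_all_spots_recovered_with_subvoxel_centroids(self, small_scene):
        spots = detect_spots(small_scene.stack_a)
        truth = small_scene.truth.positions("a")
        assert len(spots) == len(truth)
        score = evaluate_detection(spots, truth, match_radius=3.0)
        assert score.recall == 1.0 and score.precision == 1.0
        assert score.rmse <= 0.5

    def test_volume_bounds_hold_for_every_reported_spot(self, standard_detections):
        cfg = DetectionConfig()
        for spotset in standard_detections:
            for spot in spotset.spots:
                assert cfg.min_volume <= spot.volume <= cfg.max_volume

    def test_centroids_lie_inside_the_volume(self, standard_detections):
        for spotset in standard_detections:
            shape = np.array(spotset.provenance["shape"])
            cents = spotset.centroids
            assert (cents >= 0).all() and (cents <= shape - 1).all()
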