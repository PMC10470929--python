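"""Three-axes fusion, confidence coding and training utilities."""

import itertools

import numpy as np
import pytest

from mitotap.tap import (
    ConstantPredictor,
    ThresholdPredictor,
    TrainingExample,
    TrainingSet,
    bce_dice_loss,
    classify_confidence,
    edge_exclusion_mask,
    fuse_majority,
    fuse_mean,
    merge_training_set,
    predict_plane_stack,
    rank_slices_for_correction,
)
from mitotap.volumes import LabelVolume, ScalarVolume, VoxelGrid, reslice, restack


def _byte_volume(grid, rng):
    return ScalarVolume(
        grid, rng.integers(0, 256, size=grid.shape, dtype=np.uint8), vrange=(0, 255)
    )


def _prob_volume(grid, rng):
    return ScalarVolume(grid, rng.random(grid.shape), vrange=(0.0, 1.0))


class TestPredictPlaneStack:
    def test_constant_predictor_gives_uniform_volume(self, grid16, random_byte_volume):
        for axis in ("xy", "yz", "zx"):
            out = predict_plane_stack(random_byte_volume, ConstantPredictor(0.5), axis)
            assert np.all(out.values == 0.5)

    @pytest.mark.parametrize("axis", ["xy", "yz", "zx"])
    def test_matches_per_plane_brute_force(self, axis, grid16, random_byte_volume):
        predictor = ThresholdPredictor(128)
        out = predict_plane_stack(random_byte_volume, predictor, axis)
        # independent oracle: apply the predictor to every plane by hand
        planes = reslice(random_byte_volume.values, axis)
        expected = restack([(p < 128).astype(float) for p in planes], axis)
        assert np.array_equal(out.values, expected)

    def test_output_shape_contract_enforced(self, grid16, random_byte_volume):
        bad = lambda plane: np.zeros((3, 3))
        with pytest.raises(ValueError, match="contract"):
            predict_plane_stack(random_byte_volume, bad, "xy")


class TestFusion:
    def test_mean_hand_example(self, ):
        grid = VoxelGrid((1, 1, 1))
        vols = [
            ScalarVolume(grid, np.full((1, 1, 1), p)) for p in (0.6, 0.4, 0.7)
        ]
        fused = fuse_mean(*vols)
        assert fused.values[0, 0, 0] == 145  # round(255 * 0.5667)

    def test_mean_unanimous_foreground_saturates(self):
        grid = VoxelGrid((1, 1, 1))
        ones = [ScalarVolume(grid, np.ones((1, 1, 1))) for _ in range(3)]
        assert fuse_mean(*ones).values[0, 0, 0] == 255

    def test_mean_matches_per_voxel_oracle(self, grid16):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vols = [_prob_volume(grid16, rng) for _ in range(3)]
            fused = fuse_mean(*vols)
            # brute-force per-voxel loop on a subsample of coordinates
            flat = [v.values.ravel() for v in vols]
            expect = np.floor(
                255.0 * (flat[0] + flat[1] + flat[2]) / 3.0 + 0.5
            ).astype(np.uint8)
            assert np.array_equal(fused.values.ravel(), expect)

    def test_fusion_permutation_invariant(self, grid16, rng):
        vols = [_prob_volume(grid16, rng) for _ in range(3)]
        ref = fuse_mean(*vols).values
        for perm in itertools.permutations(vols):
            assert np.array_equal(fuse_mean(*perm).values, ref)

    def test_majority_truth_table(self):
        grid = VoxelGrid((1, 1, 1))
        for votes in itertools.product([0, 1], repeat=3):
            vols = [
                LabelVolume(grid, np.full((1, 1, 1), v, dtype=np.int64)) for v in votes
            ]
            out = fuse_majority(*vols).labels[0, 0, 0]
            assert out == (1 if sum(votes) >= 2 else 0)

    def test_majority_rejects_nonbinary(self):
        grid = VoxelGrid((1, 1, 1))
        two = LabelVolume(grid, np.full((1, 1, 1), 2, dtype=np.int64))
        one = LabelVolume(grid, np.ones((1, 1, 1), dtype=np.int64))
        with pytest.raises(ValueError, match="binary"):
            fuse_majority(two, one, one)

    def test_grid_mismatch_rejected(self, grid16, rng):
        other = VoxelGrid((8, 8, 8))
        with pytest.raises(ValueError, match="grid"):
            fuse_mean(
                _prob_volume(grid16, rng),
                _prob_volume(other, rng),
                _prob_volume(grid16, rng),
            )

    def test_mean_then_threshold_equals_majority_for_binary_votes(self):
        # all 8 binary vote patterns: averaging + byte thresholding must
        # agree with the explicit majority vote
        grid = VoxelGrid((1, 1, 1))
        for votes in itertools.product([0, 1], repeat=3):
            probs = [ScalarVolume(grid, np.full((1, 1, 1), float(v))) for v in votes]
            bins = [LabelVolume(grid, np.full((1, 1, 1), v, dtype=np.int64)) for v in votes]
            fg = classify_confidence(fuse_mean(*probs)).foreground[0, 0, 0]
            maj = bool(fuse_majority(*bins).labels[0, 0, 0])
            assert fg == maj


class TestConfidenceCoding:
    def test_partition_of_all_byte_values(self):
        grid = VoxelGrid((1, 1, 256))
        codes = np.arange(256, dtype=np.uint8).reshape(1, 1, 256)
        conf = classify_confidence(ScalarVolume(grid, codes, vrange=(0, 255)))
        classes = conf.classes.ravel()
        assert classes[0] == 0  # background
        assert np.all(classes[1:128] == 1)  # low confidence, incl. byte 127
        assert np.all(classes[128:] == 2)  # foreground: values exceeding 127
        # partition is total and disjoint by construction of the 3 masks
        assert (conf.foreground.sum() + conf.low_confidence.sum() + (codes == 0).sum()) == 256

    def test_boundary_bytes(self):
        grid = VoxelGrid((1, 1, 4))
        codes = np.array([[[126, 127, 128, 255]]], dtype=np.uint8)
        conf = classify_confidence(ScalarVolume(grid, codes, vrange=(0, 255)))
        assert list(conf.classes.ravel()) == [1, 1, 2, 2]

    def test_unanimous_binary_roundtrip(self, grid16, rng):
        mask = rng.random(grid16.shape) > 0.5
        probs = [ScalarVolume(grid16, mask.astype(float)) for _ in range(3)]
        conf = classify_confidence(fuse_mean(*probs))
        assert np.array_equal(conf.foreground, mask)


class TestEdgeExclusion:
    @pytest.mark.parametrize(
        "shape,fraction,kept",
        # 512: floor(0.1*512) = 51 trimmed per side -> 512 - 102 = 410 kept
        [((10, 10), 0.10, (8, 8)), ((512, 512), 0.10, (410, 410)), ((7, 9), 0.0, (7, 9))],
    )
    def test_interior_size(self, shape, fraction, kept):
        mask = edge_exclusion_mask(shape, fraction)
        ys, xs = np.nonzero(mask)
        assert (ys.max() - ys.min() + 1, xs.max() - xs.min() + 1) == kept
        assert mask.sum() == kept[0] * kept[1]

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            edge_exclusion_mask((10, 10), 0.5)


class TestBceDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        target = (rng.random((32, 32)) > 0.5).astype(float)
        assert bce_dice_loss(target, target) < 1e-5

    def test_uniform_half_prediction_closed_form(self):
        # pred uniform 0.5, target half ones: BCE = ln 2 and Dice = 1/2
        target = np.zeros((4, 4))
        target[:2] = 1.0
        loss = bce_dice_loss(np.full((4, 4), 0.5), target)
        assert loss == pytest.approx(np.log(2.0) + 0.5, rel=1e-6)

    def test_single_pixel_perturbation_increases_loss(self):
        target = np.zeros((8, 8))
        target[0, 0] = 1.0
        good = np.clip(target, 0.05, 0.95)
        worse = good.copy()
        worse[0, 0] -= 0.1  # push a correct pixel toward the wrong class
        assert bce_dice_loss(worse, target) > bce_dice_loss(good, target)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestHitlBookkeeping:
    def test_rank_by_low_confidence_fraction(self):
        grid = VoxelGrid((3, 4, 4))
        codes = np.zeros((3, 4, 4), dtype=np.uint8)
        codes[0, :, :2] = 60  # fraction 0.5... scaled per slice below
        codes[0] = 0
        codes[0, 0, 0] = 60  # slice 0: ~0.06
        codes[1, :2] = 60  # slice 1: 0.5
        codes[2, 0] = 60  # slice 2: 0.25
        conf = classify_confidence(ScalarVolume(grid, codes, vrange=(0, 255)))
        assert rank_slices_for_correction(conf) == [1, 2, 0]

    def test_ties_break_by_slice_index(self):
        grid = VoxelGrid((4, 2, 2))
        conf = classify_confidence(
            ScalarVolume(grid, np.zeros((4, 2, 2), dtype=np.uint8), vrange=(0, 255))
        )
        assert rank_slices_for_correction(conf) == [0, 1, 2, 3]

    def test_merge_appends_and_replaces(self):
        img = np.zeros((4, 4))
        lbl = np.zeros((4, 4))
        initial = TrainingSet(
            [TrainingExample(i, "xy", img, lbl, iteration=0) for i in range(3)]
        )
        corrected = [(i, "xy", img, np.ones((4, 4))) for i in (5, 6, 7)]
        merged = merge_training_set(initial, corrected, iteration=1)
        assert len(merged) == 6
        # re-correcting an existing slice replaces it, count unchanged
        again = merge_training_set(merged, [(5, "xy", img, lbl)], iteration=2)
        assert len(again) == 6
        entry = {(e.index, e.axis): e for e in again.examples}[(5, "xy")]
        assert entry.iteration == 2

    def test_merge_empty_is_identity(self):
        ts = TrainingSet(
            [TrainingExample(0, "xy", np.zeros((2, 2)), np.zeros((2, 2)), 0)]
        )
        assert merge_training_set(ts, [], iteration=3).keys() == ts.keys()
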