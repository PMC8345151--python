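"""Architecture contracts, loss arithmetic, augmentation geometry,
threshold optimization and mask post-processing."""

import numpy as np
import pytest

from pdxrad import nets
from pdxrad.phantom import PhantomSpec, generate_volume
from pdxrad.types import BinaryMask3D


@pytest.mark.parametrize("arch", nets.ARCHS)
def test_all_architectures_share_io_contract(arch, rng):
    cfg = nets.NetConfig(arch=arch, depth=2, base_filters=4, input_size=64)
    model = nets.build_network(cfg, seed=0)
    x = rng.standard_normal((2, 64, 64, 2))
    out = model.forward(x)
    assert out.data.shape == (2, 64, 64, 1)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_inference_is_deterministic(rng):
    """Dropout is disabled outside training, so forward passes repeat exactly."""
    cfg = nets.NetConfig(arch="dr2unet", depth=2, base_filters=4,
                         dropout_rate=0.5, input_size=32)
    model = nets.build_network(cfg, seed=0)
    x = rng.standard_normal((1, 32, 32, 2))
    np.testing.assert_array_equal(model.forward(x).data, model.forward(x).data)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="rcl_timesteps"):
        nets.NetConfig(rcl_timesteps=0)
    with pytest.raises(ValueError, match="divisible"):
        nets.build_network(nets.NetConfig(depth=4, input_size=100))
    with pytest.raises(ValueError, match="arch"):
        nets.NetConfig(arch="vgg")


def test_model_save_load_round_trip(tmp_path, rng):
    cfg = nets.NetConfig(arch="res_unet", depth=2, base_filters=4, input_size=32)
    model = nets.build_network(cfg, seed=3)
    x = rng.standard_normal((1, 32, 32, 2))
    before = model.forward(x).data
    model.save(tmp_path / "m.npz", threshold=0.42)
    loaded, thr = nets.SegmentationModel.load(tmp_path / "m.npz")
    assert thr == 0.42
    np.testing.assert_array_equal(loaded.forward(x).data, before)


class TestDiceLoss:
    def test_perfect_prediction(self):
        t = np.zeros((4, 4))
        t[:2] = 1
        assert nets.dice_loss(t, t) == pytest.approx(0.0)

    def test_inverted_prediction_near_one(self):
        t = np.zeros((8, 8))
        t[:4] = 1
        assert nets.dice_loss(1 - t, t) > 0.9

    def test_uniform_half_prediction_hand_arithmetic(self):
        # pred = 0.5 everywhere (N voxels), target half-full:
        # num = 2*(0.5*N/2) + 1 ; den = 0.5N + N/2 + 1
        n = 64
        t = np.zeros(n)
        t[: n // 2] = 1
        expected = 1.0 - (2 * 0.5 * (n / 2) + 1.0) / (0.5 * n + n / 2 + 1.0)
        assert nets.dice_loss(np.full(n, 0.5), t) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            nets.dice_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestAugment:
    def test_mask_stays_binary_and_shapes_preserved(self, rng):
        img = rng.random((32, 32, 2))
        msk = np.zeros((32, 32), dtype=np.uint8)
        msk[10:20, 8:18] = 1
        for aimg, amsk in nets.augment(img, msk, rng, n=10):
            assert aimg.shape == img.shape and amsk.shape == msk.shape
            assert set(np.unique(amsk)) <= {0, 1}

    def test_centroid_displacement_bounded_by_shift_fraction(self, rng):
        """A centred disk moves only by the random shift (<= 0.05 * 128 px)."""
        h = 128
        yy, xx = np.mgrid[:h, :h]
        msk = (((yy - 63.5) ** 2 + (xx - 63.5) ** 2) <= 20**2).astype(np.uint8)
        img = msk[..., None].astype(float)
        for _ in range(10):
            _, amsk = nets.augment_pair(img, msk, rng)
            c0 = np.array([63.5, 63.5])
            c1 = np.array(np.nonzero(amsk)).mean(axis=1)
            # rotations/flips fix the centre; shear fixes the centroid too
            assert np.abs(c1 - c0).max() <= 0.05 * h + 1.0

    def test_four_quarter_rotations_are_identity(self, rng):
        img = rng.random((16, 16, 1))
        out = img
        for _ in range(4):
            out = np.rot90(out, 1, axes=(0, 1))
        np.testing.assert_array_equal(out, img)


class TestOptimizeThreshold:
    def test_constructed_crossing_recovered(self):
        probs = np.linspace(0, 1, 2001)
        refs = (probs >= 0.37).astype(np.uint8)
        res = nets.optimize_threshold([probs], [refs])
        assert res.threshold == pytest.approx(0.37, abs=0.02)

    def test_perfect_predictions_tie_break_to_half(self):
        refs = np.array([0, 0, 1, 1, 0, 1])
        res = nets.optimize_threshold([refs.astype(float)], [refs])
        assert res.threshold == 0.5

    def test_recall_curve_monotone_nonincreasing(self, rng):
        probs = rng.random(5000)
        refs = (rng.random(5000) < 0.3).astype(np.uint8)
        res = nets.optimize_threshold([probs], [refs])
        assert np.all(np.diff(res.recall_curve) <= 1e-12)

    def test_degenerate_reference_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = nets.optimize_threshold([np.array([0.2, 0.8])], [np.array([0, 0])])
        assert res.threshold == 0.5


@pytest.fixture(scope="module")
def model():
    cfg = nets.NetConfig(arch="unet", depth=2, base_filters=4, input_size=32)
    return nets.build_network(cfg, seed=0)


class TestPredictAndPostprocess:
    def test_slice_stacking_order(self, model, rng):
        from pdxrad import imgio

        vol = imgio.stack_channels(
            rng.random((4, 32, 32)), rng.random((4, 32, 32)), (1.1, 0.25, 0.25)
        )
        pmap, _ = nets.predict(model, vol, 0.5)
        per_slice = [
            model.forward(vol.voxels[s : s + 1]).data[0, ..., 0] for s in range(4)
        ]
        np.testing.assert_allclose(pmap.voxels, np.stack(per_slice), atol=1e-12)

    def test_threshold_above_one_gives_empty_mask(self, model, rng):
        from pdxrad import imgio

        vol = imgio.stack_channels(
            rng.random((2, 32, 32)), rng.random((2, 32, 32)), (1, 1, 1)
        )
        _, mask = nets.predict(model, vol, 1.0 + 1e-9)
        assert mask.voxels.sum() == 0

    def test_channel_mismatch_rejected(self, model, rng):
        from pdxrad import imgio

        vol = imgio.stack_channels(None, rng.random((2, 32, 32)), (1, 1, 1))
        with pytest.raises(ValueError, match="channels"):
            nets.predict(model, vol, 0.5)

    def test_keeps_largest_component_per_slice(self):
        m = np.zeros((1, 8, 8), dtype=np.uint8)
        m[0, 0:1, 0:5] = 1  # 5 voxels
        m[0, 4:5, 0:3] = 1  # 3 voxels
        out = nets.postprocess_largest_component(BinaryMask3D(m, (1, 1, 1)))
        assert out.voxels.sum() == 5
        assert out.voxels[0, 0, 0] == 1 and out.voxels[0, 4, 0] == 0

    def test_idempotent_and_never_grows(self, small_phantom):
        _, _, gt = small_phantom
        once = nets.postprocess_largest_component(gt)
        twice = nets.postprocess_largest_component(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)
        assert once.voxels.sum() <= gt.voxels.sum()

    def test_equal_size_tie_break_deterministic(self):
        m = np.zeros((1, 6, 6), dtype=np.uint8)
        m[0, 0, 0:2] = 1  # component touching (0,0)
        m[0, 4, 3:5] = 1  # same size, later in scan order
        out = nets.postprocess_largest_component(BinaryMask3D(m, (1, 1, 1)))
        assert out.voxels[0, 0, 0] == 1 and out.voxels[0, 4, 3] == 0


@pytest.fixture(scope="module")
def tiny_subjects():
    subs = []
    for seed in range(3):
        spec = PhantomSpec(
            grid_shape=(4, 32, 32), tumor_radii=(1.6, 2.2, 2.2),
            boundary_lumpiness=0.0, noise_sigma=4.0, seed=seed,
        )
        subs.append(generate_volume(spec))
    return subs


class TestTraining:
    def test_loss_decreases_on_separable_phantoms(self, tiny_subjects):
        cfg = nets.NetConfig(arch="unet", depth=2, base_filters=4, input_size=32)
        tc = nets.TrainConfig(epochs=10, learning_rate=3e-3, batch_size=4,
                              folds=2, seed=0, augment=False)
        tm = nets.train(cfg, tiny_subjects, tc)
        losses = [h["loss"] for h in tm.history]
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.2

    def test_fold_assignments_deterministic(self):
        a = nets.fold_assignments(10, 5, seed=3)
        b = nets.fold_assignments(10, 5, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_subjects_for_folds_rejected(self, tiny_subjects):
        cfg = nets.NetConfig(arch="unet", depth=2, base_filters=4, input_size=32)
        tc = nets.TrainConfig(epochs=1, folds=5, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            nets.cross_validate(cfg, tiny_subjects, tc)
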