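import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.base import clone

from apextrack import unet
from apextrack.dataset_io import make_mask
from apextrack.segmentation_model import (NetworkConfig, TrainConfig,
                                          UNetSegmenter, build_network, infer,
                                          soft_dice_loss, train)
from apextrack.synthetic_data import SceneSpec, generate_video


def brute_force_dice(p, b):
    """Independent elementwise evaluation of the smoothed IoU loss."""
    inter = union = psum = bsum = 0.0
    for pi, bi in zip(np.ravel(p).tolist(), np.ravel(b).tolist()):
        inter += pi * bi
        psum += pi
        bsum += bi
    union = psum + bsum - inter
    return 1.0 - (inter + 1.0) / (union + 1.0)


class TestSoftDiceLoss:
    def test_perfect_overlap_is_zero(self):
        rng = np.random.default_rng(0)
        b = (rng.random((16, 16)) > 0.7).astype(float)
        assert soft_dice_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_both_empty_is_zero(self):
        z = np.zeros((8, 8))
        assert soft_dice_loss(z, z) == 0.0

    def test_hand_computed_2x2_case(self):
        p = np.full((2, 2), 0.5)
        b = np.array([[1.0, 0.0], [0.0, 0.0]])
        # 1 - (0.5 + 1) / (2 + 1 - 0.5 + 1)
        assert soft_dice_loss(p, b) == pytest.approx(1 - 1.5 / 3.5, abs=1e-12)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random((8, 8))
            b = (rng.random((8, 8)) > 0.5).astype(float)
            assert soft_dice_loss(p, b) == pytest.approx(
                brute_force_dice(p, b), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(p=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
           bbits=hnp.arrays(np.int8, (6, 6), elements=st.integers(0, 1)))
    def test_bounded_below_one(self, p, bbits):
        loss = soft_dice_loss(p, bbits.astype(float))
        assert 0.0 <= loss < 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            soft_dice_loss(np.full((2, 2), 1.5), np.zeros((2, 2)))


class TestArchitecture:
    def test_deterministic_init_under_seed(self):
        cfg = NetworkConfig(base_channels=2)
        a = build_network(cfg, 7)
        b = build_network(cfg, 7)
        c = build_network(cfg, 8)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_three_halvings_and_output_range(self):
        cfg = NetworkConfig(base_channels=2)
        params = build_network(cfg, 0)
        x = np.random.default_rng(0).random((1, 3, 48, 64)).astype(np.float32)
        prob, info = unet.forward(params, x, want_cache=False)
        assert info["bottleneck_shape"][2:] == (48 // 8, 64 // 8)
        assert prob.shape == (1, 1, 48, 64)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_indivisible_input_rejected(self):
        params = build_network(NetworkConfig(base_channels=2), 0)
        with pytest.raises(ValueError, match="divisible"):
            unet.forward(params, np.zeros((1, 3, 100, 100), dtype=np.float32))

    def test_fixed_architecture_constraints(self):
        with pytest.raises(ValueError):
            NetworkConfig(levels=3)
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=5)


@pytest.fixture(scope="module")
def params():
    return build_network(NetworkConfig(base_channels=2), 1)


class TestInfer:

    def test_odd_crop_padded_and_unpadded(self, params):
        img = np.random.default_rng(2).integers(0, 255, (101, 101, 3),
                                                dtype=np.uint8)
        p = infer(params, img)
        assert p.shape == (101, 101)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_zeroed_final_layer_gives_half_everywhere(self, params):
        params = [q.copy() for q in params]
        params[-2][:] = 0.0
        params[-1][:] = 0.0
        img = np.random.default_rng(3).integers(0, 255, (16, 16, 3),
                                                dtype=np.uint8)
        assert np.allclose(infer(params, img), 0.5)

    def test_deterministic(self, params):
        img = np.random.default_rng(4).integers(0, 255, (24, 24, 3),
                                                dtype=np.uint8)
        assert np.array_equal(infer(params, img), infer(params, img))

    def test_too_small_input_rejected(self, params):
        with pytest.raises(ValueError, match="at least"):
            infer(params, np.zeros((4, 4, 3), dtype=np.uint8))


def _crop_pairs(n_frames=50, side=16, box_side=5, seed=3):
    """Small apex-centred crops: a fast but non-trivial training problem."""
    spec = SceneSpec.reduced(seed=seed, n_frames=n_frames)
    video = generate_video(spec)
    pairs = []
    for f, a in zip(video.sequence.frames, video.annotations):
        cx, cy = int(a.x), int(a.y)
        x0 = min(max(cx - side // 2, 0), 48 - side)
        y0 = min(max(cy - side // 2, 0), 48 - side)
        pairs.append((f[y0:y0 + side, x0:x0 + side],
                      make_mask((cx - x0, cy - y0), (side, side), box_side)))
    return pairs


class TestTraining:
    def test_empty_dataset_rejected(self):
        params = build_network(NetworkConfig(base_channels=2), 0)
        with pytest.raises(ValueError, match="empty"):
            train(params, [], TrainConfig())

    def test_zero_learning_rate_is_identity(self):
        params = build_network(NetworkConfig(base_channels=2), 0)
        out, _ = train(params, _crop_pairs(8),
                       TrainConfig(learning_rate=0.0, epochs=2, seed=0))
        assert all(np.array_equal(a, b) for a, b in zip(params, out))

    def test_same_seed_bit_identical_histories(self):
        params = build_network(NetworkConfig(base_channels=2), 0)
        pairs = _crop_pairs(16)
        cfg = TrainConfig(epochs=2, seed=5)
        _, h1 = train(params, pairs, cfg)
        _, h2 = train(params, pairs, cfg)
        assert h1 == h2

    def test_loss_decreases_and_halves_within_twenty_epochs(self):
        """Seeded smoke property: >=50 pairs, mean loss halves by epoch 20."""
        params = build_network(NetworkConfig(base_channels=4), 5)
        _, hist = train(params, _crop_pairs(50),
                        TrainConfig(learning_rate=0.05, epochs=20, seed=0))
        assert hist[9] < hist[0]
        assert hist[-1] < 0.5 * hist[0]

    def test_early_stop_on_target_loss(self):
        params = build_network(NetworkConfig(base_channels=2), 0)
        _, hist = train(params, _crop_pairs(8),
                        TrainConfig(epochs=5, seed=0, target_loss=2.0))
        assert len(hist) == 1  # any loss < 2 stops after the first epoch


class TestEstimator:
    def test_sklearn_clone_and_params(self):
        est = UNetSegmenter(base_channels=3, epochs=2, seed=9)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_and_checkpoint_round_trip(self, tmp_path):
        pairs = _crop_pairs(8)
        X = np.stack([f for f, _ in pairs])
        y = np.stack([m for _, m in pairs])
        est = UNetSegmenter(base_channels=2, epochs=1, seed=0).fit(X, y)
        assert len(est.loss_history_) == 1
        prob = est.predict_proba(X[0])
        assert prob.shape == X[0].shape[:2]
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = UNetSegmenter.load(path)
        assert all(np.array_equal(a, b)
                   for a, b in zip(est.params_, loaded.params_))
        assert np.array_equal(loaded.predict_proba(X[0]), prob)

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UNetSegmenter().predict_proba(np.zeros((8, 8, 3), dtype=np.uint8))
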