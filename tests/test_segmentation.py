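import numpy as np
import pytest

from treeheight.seg import (AttentionUNet, DepthAttentionUNet, SegNetConfig,
                            augment, build_network, extract_instances,
                            normalize_depth, predict_mask, seg_metrics, train)
from treeheight.seg import nn
from treeheight.seg.network import load_weights, save_weights
from treeheight.types import DepthMap, TreeMask

TINY = SegNetConfig(input_size=32, levels=3, base_channels=4, batch_size=2,
                    learning_rate=1e-3, total_steps=5)


def _tiny_sample(rng, size=32):
    rgb = rng.integers(0, 256, size=(size, size, 3)).astype(np.uint8)
    depth = DepthMap(values=rng.uniform(500, 5000, (size, size)), kind="absolute")
    labels = np.zeros((size, size), dtype=np.int64)
    labels[8:24, 10:20] = 1
    return rgb, depth, TreeMask(labels=labels)


class TestAutodiff:
    """Numeric gradient checks for the hand-rolled layers."""

    @pytest.mark.parametrize("op_name", ["conv", "maxpool", "upsample", "gate"])
    def test_gradients_match_finite_differences(self, rng, op_name):
        x = nn.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        w = nn.Tensor(rng.normal(size=(3, 2, 3, 3)) * 0.5, requires_grad=True)
        b = nn.Tensor(rng.normal(size=(3,)), requires_grad=True)
        target = rng.random(size=(1, 3, 4, 4)) > 0.5

        def forward():
            if op_name == "conv":
                out = nn.conv2d(x, w, b)
            elif op_name == "maxpool":
                out = nn.upsample2x(nn.maxpool2x2(nn.conv2d(x, w, b)))
            elif op_name == "upsample":
                out = nn.conv2d(nn.upsample2x(nn.maxpool2x2(x)), w, b)
            else:  # attention-style gating
                c = nn.conv2d(x, w, b)
                out = nn.mul(c, nn.sigmoid(c))
            assert out.data.shape == target.shape
            return nn.bce_with_logits(out, target)

        loss = forward()
        loss.backward()
        for p in (x, w, b):
            g = p.grad.copy()
            flat = p.data.ravel()
            for idx in [0, len(flat) // 2, len(flat) - 1]:
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = forward().data
                flat[idx] = orig - eps
                lm = forward().data
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestBuildNetwork:
    def test_forward_shape_contract(self, rng):
        net = build_network(TINY, seed=0)
        out = net.forward(rng.random((1, 3, 32, 32)), rng.random((1, 1, 32, 32)))
        assert out.data.shape == (1, 1, 32, 32)

    def test_zero_depth_input_finite(self, rng):
        net = build_network(TINY, seed=0)
        out = net.forward(rng.random((1, 3, 32, 32)), np.zeros((1, 1, 32, 32)))
        assert np.all(np.isfinite(out.data))

    def test_dual_encoder_has_more_parameters_than_single(self):
        dual = DepthAttentionUNet(TINY, seed=0)
        single = AttentionUNet(TINY, seed=0)
        assert dual.n_parameters() > single.n_parameters()

    def test_depth_pathway_is_live(self, rng):
        net = build_network(TINY, seed=0)
        rgb = rng.random((1, 3, 32, 32))
        d1 = rng.random((1, 1, 32, 32))
        out1 = net.forward(rgb, d1).data
        out2 = net.forward(rgb, d1 + 0.3).data
        assert not np.allclose(out1, out2)

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SegNetConfig(input_size=100, levels=4, base_channels=4)

    def test_concat_fusion_option(self, rng):
        cfg = SegNetConfig(input_size=32, levels=3, base_channels=4,
                           fusion="concat_project")
        net = build_network(cfg, seed=0)
        out = net.forward(rng.random((1, 3, 32, 32)), rng.random((1, 1, 32, 32)))
        assert out.data.shape == (1, 1, 32, 32)

    def test_weight_round_trip(self, tmp_path, rng):
        net = build_network(TINY, seed=3)
        rgb, depth = rng.random((1, 3, 32, 32)), rng.random((1, 1, 32, 32))
        before = net.forward(rgb, depth).data
        save_weights(net, tmp_path / "w.npz")
        restored = load_weights(tmp_path / "w.npz")
        np.testing.assert_allclose(restored.forward(rgb, depth).data, before)


class TestAugment:
    def test_seed_determinism(self, rng):
        sample = _tiny_sample(rng)
        a = augment(*sample, seed=7)
        b = augment(*sample, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1].values, b[1].values)
        np.testing.assert_array_equal(a[2].labels, b[2].labels)

    def test_forced_flip_is_involution(self, rng):
        rgb, depth, mask = _tiny_sample(rng)
        once = np.flip(rgb, axis=1)
        twice = np.flip(once, axis=1)
        np.testing.assert_array_equal(twice, rgb)

    def test_labels_subset_of_original(self, rng):
        for seed in range(5):
            rgb, depth, mask = _tiny_sample(rng)
            _, _, mask_a = augment(rgb, depth, mask, seed=seed)
            assert set(np.unique(mask_a.labels)) <= set(np.unique(mask.labels))
            assert mask_a.shape == mask.shape

    def test_depth_values_not_rescaled(self, rng):
        rgb, depth, mask = _tiny_sample(rng)
        _, depth_a, _ = augment(rgb, depth, mask, seed=3)
        # nearest-neighbor resampling: every output value existed in the input
        assert np.isin(depth_a.values[depth_a.valid],
                       depth.values[depth.valid]).all()


class TestTraining:
    def test_loss_decreases_and_is_seeded(self, rng):
        data = [_tiny_sample(rng) for _ in range(2)]
        cfg = SegNetConfig(input_size=32, levels=3, base_channels=4,
                           batch_size=2, learning_rate=1e-3, total_steps=15)
        net, losses = train(data, cfg, seed=0)
        assert losses[-1] < losses[0]
        _, losses2 = train(data, cfg, seed=0)
        np.testing.assert_allclose(losses, losses2)
        _, losses3 = train(data, cfg, seed=1)
        assert not np.allclose(losses, losses3)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TINY, seed=0)

    def test_inconsistent_sizes_rejected(self, rng):
        data = [_tiny_sample(rng, 32), _tiny_sample(rng, 16)]
        with pytest.raises(ValueError, match="sizes"):
            train(data, TINY, seed=0)


class TestSegMetrics:
    def test_identical_masks(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        out = seg_metrics(m, m)
        assert out.iou == 100.0 and out.pixel_accuracy == 100.0

    def test_hand_counted_2x2(self):
        pred = np.array([[1, 1], [0, 0]])
        truth = np.array([[1, 0], [0, 0]])
        out = seg_metrics(pred, truth)
        assert out.iou == 50.0
        assert out.pixel_accuracy == 75.0

    def test_disjoint_masks(self):
        pred = np.array([[1, 0], [0, 0]])
        truth = np.array([[0, 0], [0, 1]])
        assert seg_metrics(pred, truth).iou == 0.0

    def test_both_empty_defined_as_100(self):
        z = np.zeros((3, 3), dtype=int)
        assert seg_metrics(z, z).iou == 100.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            pred = rng.random((9, 7)) > 0.5
            truth = rng.random((9, 7)) > 0.5
            inter = union = correct = 0
            for i in range(9):
                for j in range(7):
                    inter += pred[i, j] and truth[i, j]
                    union += pred[i, j] or truth[i, j]
                    correct += pred[i, j] == truth[i, j]
            out = seg_metrics(pred, truth)
            assert out.iou == pytest.approx(100.0 * inter / union)
            assert out.pixel_accuracy == pytest.approx(100.0 * correct / 63)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            seg_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


class TestExtractInstances:
    def test_single_blob(self):
        b = np.zeros((8, 8), dtype=bool)
        b[2:5, 2:5] = True
        out = extract_instances(b)
        assert out.n_instances == 1

    def test_area_ordering(self):
        b = np.zeros((20, 20), dtype=bool)
        b[0:10, 0:10] = True      # area 100
        b[15:20, 10:20] = True    # area 50
        out = extract_instances(b)
        assert (out.labels[2, 2]) == 1
        assert (out.labels[17, 15]) == 2

    def test_min_area_drops_specks(self):
        b = np.zeros((10, 10), dtype=bool)
        b[0:4, 0:4] = True
        b[8, 8] = True
        out = extract_instances(b, min_area=2)
        assert out.n_instances == 1
        assert out.labels[8, 8] == 0

    def test_diagonal_blobs_are_separate(self):
        b = np.zeros((4, 4), dtype=bool)
        b[0, 0] = b[1, 1] = True  # touch only diagonally: 4-connectivity splits
        out = extract_instances(b)
        assert out.n_instances == 2


class TestNormalizeDepth:
    def test_range_and_invalid_handling(self):
        values = np.array([[100.0, 200.0], [300.0, 0.0]])
        out = normalize_depth(DepthMap(values=values, kind="absolute"))
        assert out[0, 0] == 0.0
        assert out[1, 0] == 1.0
        assert out[1, 1] == 0.0  # invalid pixel

    def test_constant_map(self):
        out = normalize_depth(DepthMap(values=np.full((2, 2), 5.0), kind="relative"))
        assert np.all(out == 0.5)
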