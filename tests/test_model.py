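"""Architecture contracts: the layer shape table, parameter tally,
deterministic initialisation, checkpointing, and the FC-to-convolution
transformation with its dense/patch equivalence."""

import numpy as np
import pytest

from he2ihc.checkpoint import load_checkpoint, save_checkpoint
from he2ihc.nn import (
    NetworkSpec,
    build_classifier,
    convert_to_fully_convolutional,
    expected_parameter_count,
    layer_output_shape,
    score_map_size,
)
from he2ihc.training import normalize_images

# layer name -> (input CxHxW, output CxHxW) for a 64x64 patch
LAYER_TABLE = {
    "conv1": ((3, 64, 64), (64, 32, 32)),
    "pool1": ((64, 32, 32), (64, 16, 16)),
    "layer1": ((64, 16, 16), (64, 16, 16)),
    "layer2": ((64, 16, 16), (128, 8, 8)),
    "layer3": ((128, 8, 8), (256, 4, 4)),
    "layer4": ((256, 4, 4), (512, 2, 2)),
    "FC": ((512, 2, 2), (3, 1, 1)),
}


class TestShapeArithmetic:
    def test_64px_input_reproduces_reference_layer_table(self):
        rows = layer_output_shape(NetworkSpec(), (64, 64))
        assert {name: (i, o) for name, i, o in rows} == LAYER_TABLE

    def test_96px_input_yields_2x2_dense_map(self):
        rows = layer_output_shape(NetworkSpec(), (96, 96))
        assert rows[-2][2] == (512, 3, 3)  # layer4 on 96 px
        assert score_map_size(NetworkSpec(), 96) == 2

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            layer_output_shape(NetworkSpec(), (63, 64))
        with pytest.raises(ValueError):
            score_map_size(NetworkSpec(), 32)

    def test_score_map_size_is_monotone(self):
        spec = NetworkSpec()
        sizes = [score_map_size(spec, h) for h in range(64, 300)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert score_map_size(spec, 64) == 1


class TestClassifier:
    def test_forward_gives_three_scores_per_patch(self):
        net = build_classifier(seed=0)
        x = np.random.default_rng(0).normal(size=(2, 3, 64, 64)).astype(np.float32)
        assert net.forward(x, train=False).shape == (2, 3)

    def test_wrong_channel_count_rejected(self):
        net = build_classifier(seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 64, 64), np.float32))

    def test_same_seed_gives_identical_initial_parameters(self):
        a, b = build_classifier(seed=5), build_classifier(seed=5)
        for (ka, la, pa), (kb, lb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(la.params[pa], lb.params[pb])
        c = build_classifier(seed=6)
        assert not np.array_equal(
            a.trunk.conv1.params["W"], c.trunk.conv1.params["W"]
        )

    def test_parameter_count_matches_independent_tally(self):
        """Arithmetic tally over the layer table, written out long-hand."""
        def conv_p(cin, cout, k):
            return cin * cout * k * k

        def bn_p(c):
            return 2 * c

        def block_p(cin, cout, downsample):
            p = conv_p(cin, cout, 3) + bn_p(cout) + conv_p(cout, cout, 3) + bn_p(cout)
            if downsample:
                p += conv_p(cin, cout, 1) + bn_p(cout)
            return p

        total = conv_p(3, 64, 7) + bn_p(64)
        total += block_p(64, 64, False) + block_p(64, 64, False)
        total += block_p(64, 128, True) + block_p(128, 128, False)
        total += block_p(128, 256, True) + block_p(256, 256, False)
        total += block_p(256, 512, True) + block_p(512, 512, False)
        total += 512 * 2 * 2 * 3 + 3  # final fully connected layer
        net = build_classifier(seed=0)
        assert net.num_parameters() == total
        assert expected_parameter_count(NetworkSpec()) == total

    def test_checkpoint_round_trip_preserves_outputs(self, tmp_path):
        net = build_classifier(seed=1)
        x = np.random.default_rng(1).normal(size=(2, 3, 64, 64)).astype(np.float32)
        want = net.forward(x, train=False)
        save_checkpoint(net, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(loaded.forward(x, train=False), want)


class TestFullyConvolutionalTransform:
    def test_dense_equals_classifier_on_training_geometry(self):
        net = build_classifier(seed=2)
        dense = convert_to_fully_convolutional(net)
        x = np.random.default_rng(2).normal(size=(8, 3, 64, 64)).astype(np.float32)
        patch_scores = net.forward(x, train=False)
        dense_scores = dense.forward(x, train=False)
        assert dense_scores.shape == (8, 3, 1, 1)
        assert np.abs(dense_scores[:, :, 0, 0] - patch_scores).max() < 1e-5

    def test_kernel_is_exact_reshape_of_fc_weights(self):
        net = build_classifier(seed=3)
        dense = convert_to_fully_convolutional(net)
        np.testing.assert_array_equal(
            dense.head.params["W"].reshape(3, -1), net.fc.params["W"]
        )
        np.testing.assert_array_equal(dense.head.params["b"], net.fc.params["b"])

    def test_larger_input_maps_to_predicted_grid(self):
        dense = convert_to_fully_convolutional(build_classifier(seed=4))
        x = np.random.default_rng(4).normal(size=(1, 3, 96, 96)).astype(np.float32)
        assert dense.forward(x, train=False).shape == (1, 3, 2, 2)

    def test_conversion_requires_classifier(self):
        with pytest.raises(TypeError):
            convert_to_fully_convolutional(object())

    def test_dense_scores_equal_receptive_field_crops(self, trained_model, roi_pair):
        """Exact sliding-window property: the dense score at grid (i, j)
        equals a fresh dense pass over the crop containing that position's
        full receptive field (clipped at image borders).  This is the
        brute-force per-position oracle for the dense scan."""
        from he2ihc.nn import receptive_interval

        net, _, _, _ = trained_model
        dense = convert_to_fully_convolutional(net)
        he, _, _ = roi_pair
        x = normalize_images(he[None])
        scores = dense.forward(x, train=False)[0]
        stride, lo, hi = receptive_interval(dense.spec)
        h, w = x.shape[2:]
        rng = np.random.default_rng(0)
        gh, gw = scores.shape[1:]
        margin = -(-(-lo) // stride)
        for _ in range(6):
            i = int(rng.integers(0, gh))
            j = int(rng.integers(0, gw))
            r0 = stride * max(0, i - margin)
            c0 = stride * max(0, j - margin)
            crop = x[:, :, r0 : min(h, stride * i + hi + 1), c0 : min(w, stride * j + hi + 1)]
            tile = dense.forward(crop, train=False)[0]
            got = tile[:, i - r0 // stride, j - c0 // stride]
            np.testing.assert_allclose(got, scores[:, i, j], atol=1e-3)

    def test_dense_map_agrees_with_sliding_window_patch_route_on_majority(
        self, trained_model, roi_pair
    ):
        """Dense scanning and isolated-patch inference agree on the majority
        of interior windows, but not window-by-window: the dense pass sees
        real tissue throughout its 467-px receptive field where the patch
        route sees zero padding, and that context legitimately changes
        verdicts on off-center windows.  Aggregate map quality is what the
        quantification correlations measure."""
        net, _, _, _ = trained_model
        dense = convert_to_fully_convolutional(net)
        he, _, _ = roi_pair
        x = normalize_images(he[None])
        dense_arg = dense.forward(x, train=False)[0].argmax(axis=0)
        gh, gw = dense_arg.shape
        crops, positions = [], []
        for i in range(1, gh - 1):
            for j in range(1, gw - 1):
                crops.append(x[0, :, 32 * i : 32 * i + 64, 32 * j : 32 * j + 64])
                positions.append((i, j))
        patch_arg = net.forward(np.stack(crops), train=False).argmax(axis=1)
        matches = np.array(
            [dense_arg[i, j] == p for (i, j), p in zip(positions, patch_arg)]
        )
        assert matches.mean() > 0.5
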