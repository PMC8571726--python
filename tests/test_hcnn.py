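"""Network construction, normalization, forward recording and training."""

import numpy as np
import pytest

from numsense import hcnn


def lrn_loop_oracle(a, params):
    """Naive triple-loop reference for lateral-inhibition normalization."""
    a = np.asarray(a, dtype=np.float64)
    C, H, W = a.shape
    out = np.empty_like(a)
    half = params.n // 2
    for i in range(C):
        lo, hi = max(0, i - half), min(C - 1, i + half)
        for y in range(H):
            for x in range(W):
                s = sum(max(0.0, a[j, y, x]) ** 2 for j in range(lo, hi + 1))
                out[i, y, x] = a[i, y, x] / (params.k + params.alpha * s) ** params.beta
    return out


class TestArchitecture:
    def test_default_config_final_layer_units(self):
        cfg = hcnn.default_config()
        maps, h, w = cfg.feature_shape(13)
        assert (maps, h, w) == (768, 7, 7)
        assert maps * h * w == 37_632

    def test_spatial_chain_telescopes(self):
        cfg = hcnn.default_config()
        sizes = [s.spatial_size for s in cfg.layers if s.role == "convolutional"]
        assert sizes == [224, 112, 56, 28, 14, 7, 7, 7]

    def test_inconsistent_chain_rejected(self):
        cfg = hcnn.default_config()
        bad = cfg.layers.copy()
        bad[3] = hcnn.LayerSpec(3, "convolutional", 48, 90, 9)
        with pytest.raises(hcnn.ConfigurationError, match="layer 3"):
            hcnn.NetworkConfig(layers=bad).validate()

    def test_non_canonical_needs_reduced_flag(self):
        cfg = hcnn.tiny_config()
        with pytest.raises(hcnn.ConfigurationError, match="canonical"):
            hcnn.NetworkConfig(layers=cfg.layers, n_classes=10).validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = hcnn.default_config()
        path = tmp_path / "net.yaml"
        hcnn.config_to_yaml(cfg, str(path))
        back = hcnn.config_from_yaml(str(path))
        assert back.layers == cfg.layers

    def test_seeded_build_determinism(self):
        cfg = hcnn.tiny_config()
        a = hcnn.build_network(cfg, seed=7)
        b = hcnn.build_network(cfg, seed=7)
        c = hcnn.build_network(cfg, seed=8)
        for pa, pb in zip(a.conv_stages(), b.conv_stages()):
            np.testing.assert_array_equal(pa.W, pb.W)
        assert not np.array_equal(a.conv_stages()[0].W, c.conv_stages()[0].W)

    def test_default_lrn_on_first_two_conv_stages(self):
        net = hcnn.build_network(hcnn.tiny_config(), seed=0)
        assert net.lrn_layers == (1, 3)


class TestLRN:
    def test_all_zero_input(self):
        out = hcnn.local_response_normalize(np.zeros((4, 3, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_map_scalar_formula(self):
        a = np.ones((1, 1, 1))
        out = hcnn.local_response_normalize(a, hcnn.LRNParams())
        expected = 1.0 / (2.0 + 1e-4) ** 0.75
        assert out[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("shape,seed", [((3, 4, 4), 0), ((8, 8, 8), 1), ((5, 2, 7), 2)])
    def test_matches_loop_oracle(self, shape, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=shape)
        params = hcnn.LRNParams()
        out = hcnn.local_response_normalize(a, params)
        np.testing.assert_allclose(out, lrn_loop_oracle(a, params), atol=1e-10)

    def test_channel_last_axis_agrees(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 5, 6))
        first = hcnn.local_response_normalize(a, channel_axis=0)
        last = hcnn.local_response_normalize(
            np.moveaxis(a, 0, -1), channel_axis=-1
        )
        np.testing.assert_allclose(np.moveaxis(last, -1, 0), first, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            hcnn.local_response_normalize(np.full((2, 2, 2), np.nan))
        with pytest.raises(hcnn.ConfigurationError):
            hcnn.local_response_normalize(np.ones((2, 2, 2)), hcnn.LRNParams(k=0.0))
        with pytest.raises(hcnn.ConfigurationError):
            hcnn.local_response_normalize(np.ones((2, 2, 2)), hcnn.LRNParams(beta=-1))


class TestConvolution:
    def test_fft_path_matches_im2col(self):
        net = hcnn.build_network(hcnn.tiny_config(), seed=1)
        st = net.conv_stages()[0]
        x = np.random.default_rng(0).random((2, 64, 64, 3)).astype(np.float32)
        fft = hcnn._conv_same_fft(x, st) + st.bias
        direct = hcnn._conv_same(x, st, allow_fft=False)
        np.testing.assert_allclose(fft, direct, atol=2e-5)

    def test_col2im_is_adjoint_of_im2col(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 6, 6, 3))
        k = 3
        col = hcnn._im2col(x, k)
        g = rng.normal(size=col.shape)
        # <im2col(x), g> == <x, col2im(g)>
        lhs = float(np.sum(col * g))
        rhs = float(np.sum(x * hcnn._col2im(g, x.shape, k)))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestForwardRecord:
    def test_unit_count_and_coords(self, tiny_net):
        img = np.zeros((64, 64), np.float32)
        acts = hcnn.forward_record(tiny_net, img, noise=hcnn.NoiseParams(enabled=False))
        maps, h, w = tiny_net.config.feature_shape(13)
        assert acts.values.shape == (maps * h * w, 1)
        # the (map, row, col) decomposition covers every coordinate once
        coords = {tuple(c) for c in acts.unit_coords}
        assert len(coords) == maps * h * w
        assert acts.unit_coords[:, 0].max() == maps - 1

    def test_deterministic_without_noise(self, tiny_net):
        img = np.random.default_rng(0).random((2, 64, 64)).astype(np.float32)
        a = hcnn.forward_record(tiny_net, img, noise=hcnn.NoiseParams(enabled=False))
        b = hcnn.forward_record(tiny_net, img, noise=hcnn.NoiseParams(enabled=False))
        np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_noise_equals_disabled(self, tiny_net):
        img = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        a = hcnn.forward_record(tiny_net, img, noise=hcnn.NoiseParams(1.0, 0.0, True))
        b = hcnn.forward_record(tiny_net, img, noise=hcnn.NoiseParams(enabled=False))
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_noise_varies_blank_display_responses(self, tiny_net):
        blank = np.zeros((40, 64, 64), np.float32)
        acts = hcnn.forward_record(tiny_net, blank, seed=9)
        responding = acts.values[acts.values.max(axis=1) > 0]
        assert len(responding)  # conv biases give nonzero blank responses
        assert np.unique(responding, axis=1).shape[1] == 40

    def test_seeded_noise_is_reproducible(self, tiny_net):
        img = np.random.default_rng(2).random((3, 64, 64)).astype(np.float32)
        a = hcnn.forward_record(tiny_net, img, seed=5)
        b = hcnn.forward_record(tiny_net, img, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rectified_nonnegative(self, tiny_net):
        img = np.random.default_rng(3).random((2, 64, 64)).astype(np.float32)
        acts = hcnn.forward_record(tiny_net, img, seed=1)
        assert acts.values.min() >= 0
        assert np.all(np.isfinite(acts.values))

    def test_wrong_image_size_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="expects 64x64"):
            hcnn.forward_record(tiny_net, np.zeros((32, 32), np.float32))

    def test_activation_io_roundtrip(self, tiny_net, tmp_path):
        img = np.random.default_rng(4).random((2, 64, 64)).astype(np.float32)
        acts = hcnn.forward_record(tiny_net, img, seed=2)
        path = tmp_path / "acts.h5"
        hcnn.save_activations(acts, str(path))
        back = hcnn.load_activations(str(path))
        np.testing.assert_array_equal(back.values, acts.values)
        assert back.layer_index == acts.layer_index
        assert back.attrs["noise_sigma"] == pytest.approx(0.15)


class TestBatchNorm:
    def test_calibration_standardizes_first_stage(self, tiny_net):
        import copy

        net = copy.deepcopy(tiny_net)
        x = np.random.default_rng(0).random((8, 64, 64)).astype(np.float32)
        hcnn.calibrate_batch_norm(net, x)
        st = net.conv_stages()[0]
        z = hcnn._conv_same(hcnn._as_batch(x, net.config), st)
        zh = (z - st.running_mean) / np.sqrt(st.running_var + 1e-5)
        np.testing.assert_allclose(zh.mean(axis=(0, 1, 2)), 0.0, atol=1e-3)
        np.testing.assert_allclose(zh.std(axis=(0, 1, 2)), 1.0, atol=1e-2)
        assert net.bn_calibrated


class TestClassifierHead:
    def test_probabilities_normalized(self, tiny_net):
        img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        p = hcnn.predict_proba(tiny_net, img)
        assert p.shape == (1, 10)
        assert p.sum() == pytest.approx(1.0, abs=1e-5)

    def test_top_k_sorted_and_near_uniform_when_untrained(self, tiny_net):
        img = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        top = hcnn.top_k_predictions(tiny_net, img, k=5)
        conf = [c for _, c in top]
        assert len(top) == 5
        assert all(a >= b for a, b in zip(conf, conf[1:]))
        # untrained network: logits are near zero, confidences near 1/n
        full = hcnn.top_k_predictions(tiny_net, img, k=10)
        assert sum(c for _, c in full) == pytest.approx(1.0, abs=1e-5)
        assert all(abs(c - 0.1) < 0.05 for _, c in full)

    def test_top_k_argument_validation(self, tiny_net):
        img = np.zeros((64, 64), np.float32)
        with pytest.raises(ValueError):
            hcnn.top_k_predictions(tiny_net, img, k=0)
        with pytest.raises(ValueError):
            hcnn.top_k_predictions(tiny_net, img, k=11)


def _micro_net():
    """A very small network (32px input) in float64 for gradient checks."""
    cfg = hcnn.tiny_config(input_size=32, n_classes=3)
    return hcnn.build_network(cfg, seed=3, dtype=np.float64)


def _loss_of(net, x, y):
    probs, _ = hcnn._forward_train(net, x)
    return -float(np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


class TestTraining:
    def test_backprop_matches_finite_differences(self):
        net = _micro_net()
        rng = np.random.default_rng(0)
        x = rng.random((4, 32, 32, 3))
        y = np.array([0, 1, 2, 0])
        probs, caches = hcnn._forward_train(net, x)
        names = hcnn._param_names(net)
        grads = {k: np.zeros_like(v) for k, v in names.items()}
        hcnn._backward_train(net, probs, y, caches, grads)
        eps = 1e-6
        for pname, flat_idx in [("W13", 5), ("gamma9", 1), ("bias5", 0), ("fc_W", 7)]:
            p = names[pname]
            idx = np.unravel_index(flat_idx % p.size, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = _loss_of(net, x, y)
            p[idx] = orig - eps
            lm = _loss_of(net, x, y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[pname][idx] == pytest.approx(num, rel=2e-3, abs=1e-7)

    def test_loss_decreases_on_tiny_fixture(self, tmp_path):
        from PIL import Image

        rng = np.random.default_rng(0)
        root = tmp_path / "imgs"
        # three synthetic classes with distinct luminance/texture statistics
        for ci, cname in enumerate(["dark", "mid", "bright"]):
            d = root / cname
            d.mkdir(parents=True)
            for i in range(20):
                base = 40 + 80 * ci
                arr = np.clip(
                    base + 25 * rng.standard_normal((32, 32, 3)), 0, 255
                ).astype(np.uint8)
                Image.fromarray(arr).save(d / f"{i}.png")
        net = hcnn.build_network(hcnn.tiny_config(32, n_classes=3), seed=0)
        cfg = hcnn.TrainConfig(epochs=2, batch_size=20, learning_rate=0.02)
        net, log = hcnn.train_object_recognition(
            net, str(root), cfg, seed=0, checkpoint_dir=str(tmp_path / "ckpt")
        )
        assert len(log["epoch_loss"]) == 2
        assert log["epoch_loss"][1] < log["epoch_loss"][0]
        assert (tmp_path / "ckpt" / "epoch001.h5").exists()

    def test_zero_learning_rate_keeps_weights(self, tmp_path):
        from PIL import Image

        root = tmp_path / "imgs"
        for cname in ["a", "b"]:
            d = root / cname
            d.mkdir(parents=True)
            for i in range(4):
                Image.fromarray(
                    np.full((32, 32, 3), 100 if cname == "a" else 200, np.uint8)
                ).save(d / f"{i}.png")
        net = hcnn.build_network(hcnn.tiny_config(32, n_classes=3), seed=1)
        before = {k: v.copy() for k, v in hcnn._param_names(net).items()}
        cfg = hcnn.TrainConfig(epochs=1, batch_size=8, learning_rate=0.0)
        net, _ = hcnn.train_object_recognition(net, str(root), cfg, seed=0)
        for k, v in hcnn._param_names(net).items():
            np.testing.assert_array_equal(v, before[k])

    def test_missing_dataset_mentions_untrained_analyses(self, tiny_net):
        with pytest.raises(FileNotFoundError, match="untrained"):
            hcnn.train_object_recognition(tiny_net, "/nonexistent/path")

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = hcnn.tiny_config()
        net = hcnn.build_network(cfg, seed=5)
        path = tmp_path / "net.h5"
        hcnn.save_checkpoint(net, str(path))
        other = hcnn.build_network(cfg, seed=6)
        hcnn.load_checkpoint(other, str(path))
        np.testing.assert_array_equal(
            other.conv_stages()[0].W, net.conv_stages()[0].W
        )
        mismatched = hcnn.build_network(hcnn.tiny_config(n_classes=4), seed=0)
        with pytest.raises(hcnn.ConfigurationError, match="architecture"):
            hcnn.load_checkpoint(mismatched, str(path))
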