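import numpy as np
import pytest

from dfcn.arch import ArchitectureSpec, LayerSpec, build_variant
from dfcn.network import (bilinear_kernel, copy_matching_parameters, forward,
                          forward_backward, init_network, predict_labels,
                          softmax_cross_entropy)
from dfcn.windowing import WindowSpec

W = 1 / 16  # reduced width keeps these tests fast


class TestInit:
    def test_same_seed_bitwise_identical(self):
        arch = build_variant("fcn8s", 5, W)
        a = init_network(arch, seed=11)
        b = init_network(arch, seed=11)
        assert a.params.keys() == b.params.keys()
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k]), k

    def test_different_seed_differs(self):
        arch = build_variant("fcn32s", 5, W)
        a = init_network(arch, seed=1)
        b = init_network(arch, seed=2)
        assert any(not np.array_equal(a.params[k], b.params[k])
                   for k in a.params if k.startswith("conv"))

    def test_score_layers_zero(self):
        net = init_network(build_variant("fcn8s", 5, W), seed=0)
        for k, v in net.params.items():
            if k.startswith("score"):
                assert np.all(v == 0), k

    def test_bilinear_2x_kernel_closed_form(self):
        filt = bilinear_kernel(2)
        expected = np.outer([0.25, 0.75, 0.75, 0.25], [0.25, 0.75, 0.75, 0.25])
        np.testing.assert_allclose(filt, expected)

    def test_upsample_initialised_to_bilinear_identity(self):
        net = init_network(build_variant("dfcn4s", 3, W), seed=0)
        w = net.params["upscore_stage1.w"]
        np.testing.assert_allclose(w[0, 0], bilinear_kernel(2))
        assert np.all(w[0, 1] == 0)

    def test_bilinear_upsample_interpolates_constant_exactly(self):
        # identity-bilinear transposed conv must preserve a constant map
        from dfcn.network import convT_forward

        w = np.zeros((1, 1, 4, 4), dtype=np.float32)
        w[0, 0] = bilinear_kernel(2)
        x = np.full((1, 1, 6, 6), 3.0, dtype=np.float32)
        y = convT_forward(x, w, 2)
        assert y.shape == (1, 1, 12, 12)
        np.testing.assert_allclose(y[0, 0, 2:-2, 2:-2], 3.0, rtol=1e-6)

    def test_load_params_shape_check(self):
        net = init_network(build_variant("fcn32s", 3, W), seed=0)
        with pytest.raises(ValueError):
            net.load_params({"fc7.b": np.zeros(999, dtype=np.float32)})
        with pytest.raises(KeyError):
            net.load_params({"nope.w": np.zeros(1)})


class TestForward:
    @pytest.mark.parametrize("variant", ["fcn32s", "fcn16s", "fcn8s",
                                         "dfcn16s", "dfcn8s", "dfcn4s"])
    def test_shape_contract(self, variant, rng):
        net = init_network(build_variant(variant, 5, W), seed=0)
        x = rng.uniform(-1000, 1000, size=(2, 1, 64, 64)).astype(np.float32)
        out = forward(net, x)
        assert out.shape == (2, 5, 64, 64)

    def test_non_divisible_input_rejected(self, rng):
        net = init_network(build_variant("fcn32s", 3, W), seed=0)
        with pytest.raises(ValueError):
            forward(net, rng.uniform(size=(1, 1, 60, 60)).astype(np.float32))

    def test_deterministic(self, rng):
        net = init_network(build_variant("dfcn8s", 3, W), seed=0)
        x = rng.uniform(-500, 500, size=(1, 1, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(forward(net, x), forward(net, x))

    def test_translation_invariance_small_net(self, rng):
        # constant input -> interior outputs identical (engine-level contract,
        # checked on a small net whose receptive field fits the image)
        arch = ArchitectureSpec(
            variant="fcn32s", n_classes=2,
            layers=[
                LayerSpec("window", "window", in_channels=1, out_channels=3),
                LayerSpec("c1", "conv", kernel=3, in_channels=3, out_channels=4,
                          activation="relu"),
                LayerSpec("c2", "conv", kernel=3, in_channels=4, out_channels=2,
                          dilation=2),
            ],
            window=WindowSpec(-300, 600, 3))
        net = init_network(arch, seed=3)
        for k in net.params:  # randomize; init convs already random
            if k == "c2.w":
                net.params[k] = rng.normal(0, 0.5, net.params[k].shape).astype(np.float32)
        x = np.full((1, 1, 16, 16), 150.0, dtype=np.float32)
        out = forward(net, x)
        margin = 3  # half the 7-pixel receptive field
        interior = out[0, :, margin:-margin, margin:-margin]
        ref = interior[:, :1, :1]
        np.testing.assert_allclose(interior, np.broadcast_to(ref, interior.shape),
                                   rtol=1e-5, atol=1e-6)

    def test_forward_upto_intermediate(self, rng):
        net = init_network(build_variant("fcn32s", 3, W), seed=0)
        x = rng.uniform(-500, 500, size=(1, 1, 64, 64)).astype(np.float32)
        score = forward(net, x, upto="score_fr")
        assert score.shape == (1, 3, 2, 2)  # 64 / 32


class TestAtrousEquivalence:
    def test_dfcn_matches_fcn32s_on_shared_weights(self, rng):
        base = init_network(build_variant("fcn32s", 4, W), seed=5)
        base.params["score_fr.w"] = rng.normal(
            0, 0.05, base.params["score_fr.w"].shape).astype(np.float32)
        x = rng.uniform(-1000, 1200, size=(1, 1, 64, 64)).astype(np.float32)
        s32 = forward(base, x, upto="score_fr")
        for variant, sub in (("dfcn16s", 2), ("dfcn8s", 4), ("dfcn4s", 8)):
            net = init_network(build_variant(variant, 4, W), seed=5)
            copied = copy_matching_parameters(base, net)
            assert any(k.startswith("conv") for k in copied)
            sd = forward(net, x, upto="score_fr")
            assert np.abs(sd[:, :, ::sub, ::sub] - s32).max() < 1e-4, variant


class TestPredictLabels:
    def test_argmax(self):
        scores = np.zeros((2, 3, 3))
        scores[1, 0, 0] = 0.9
        scores[0, 0, 0] = 0.1
        assert predict_labels(scores)[0, 0] == 1

    def test_tie_breaks_to_lowest_class(self):
        scores = np.full((3, 2, 2), 0.5)
        assert np.all(predict_labels(scores) == 0)

    def test_all_zero_scores_all_background(self):
        assert np.all(predict_labels(np.zeros((1, 5, 4, 4))) == 0)

    def test_batched_axis(self):
        scores = np.zeros((2, 3, 2, 2))
        scores[:, 2] = 1.0
        assert np.all(predict_labels(scores) == 2)


class TestLossAndGradients:
    def test_cross_entropy_uniform_scores(self):
        scores = np.zeros((1, 4, 2, 2), dtype=np.float32)
        labels = np.zeros((1, 2, 2), dtype=np.intp)
        loss, grad = softmax_cross_entropy(scores, labels)
        assert loss == pytest.approx(np.log(4), rel=1e-5)
        assert grad.shape == scores.shape

    def test_score_gradient_matches_finite_difference(self, rng):
        # the loss is smooth in the scores: exact finite-difference check
        scores = rng.normal(0, 1, size=(1, 3, 2, 2)).astype(np.float64)
        labels = rng.integers(0, 3, size=(1, 2, 2))
        _, grad = softmax_cross_entropy(scores, labels)
        eps = 1e-5
        for idx in [(0, 0, 0, 0), (0, 1, 1, 0), (0, 2, 1, 1)]:
            sp = scores.copy(); sp[idx] += eps
            sm = scores.copy(); sm[idx] -= eps
            lp, _ = softmax_cross_entropy(sp, labels)
            lm, _ = softmax_cross_entropy(sm, labels)
            num = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_class_weights_rescale_loss(self, rng):
        scores = rng.normal(0, 1, size=(1, 3, 4, 4)).astype(np.float32)
        labels = np.zeros((1, 4, 4), dtype=np.intp)
        l1, _ = softmax_cross_entropy(scores, labels)
        l2, _ = softmax_cross_entropy(scores, labels, class_weights=[2.0, 1.0, 1.0])
        # all pixels are class 0: weight normalisation cancels
        assert l2 == pytest.approx(l1, rel=1e-6)

    def test_forward_backward_produces_all_grads(self, rng):
        net = init_network(build_variant("fcn8s", 3, W), seed=1)
        x = rng.uniform(-500, 500, size=(1, 1, 64, 64)).astype(np.float32)
        lab = rng.integers(0, 3, size=(1, 64, 64))
        grads, loss, scores = forward_backward(net, x, lab)
        assert np.isfinite(loss)
        assert scores.shape == (1, 3, 64, 64)
        assert set(grads) == set(net.params)
        for k, g in grads.items():
            assert g.shape == net.params[k].shape, k
            assert np.all(np.isfinite(g)), k

    def test_directional_derivative(self, rng):
        # smooth-path check: perturb only the score layer (no ReLU/pool kinks
        # between it and the loss) and compare against finite differences
        net = init_network(build_variant("dfcn4s", 3, 1 / 32), seed=1)
        x = rng.uniform(-1000, 1000, size=(1, 1, 32, 32)).astype(np.float32)
        lab = rng.integers(0, 3, size=(1, 32, 32))
        net.params["score_fr.w"] = rng.normal(
            0, 0.1, net.params["score_fr.w"].shape).astype(np.float32)
        grads, _, _ = forward_backward(net, x, lab)
        d = rng.normal(0, 1, net.params["score_fr.w"].shape).astype(np.float32)
        gdot = float((grads["score_fr.w"] * d).sum())
        eps = 1e-3
        orig = net.params["score_fr.w"].copy()

        def loss_at(delta):
            net.params["score_fr.w"] = orig + delta
            s = forward(net, x)
            l, _ = softmax_cross_entropy(s.astype(np.float64), lab)
            return l

        num = (loss_at(eps * d) - loss_at(-eps * d)) / (2 * eps)
        net.params["score_fr.w"] = orig
        assert gdot == pytest.approx(num, rel=5e-2)
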