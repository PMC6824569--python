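import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sinoct.training as training
from sinoct.evaluation import psnr, support_mask
from sinoct.fbp import fbp_reconstruct
from sinoct.geometry import Sinogram, embed_incomplete, subsample_views
from sinoct.network import build_unet
from sinoct.network.layers import Conv2D
from sinoct.phantoms import (
    EllipsePhantom,
    EllipseSpec,
    analytic_fan_projection,
)
from sinoct.training import (
    NadamOptimizer,
    TrainConfig,
    decayed_learning_rate,
    dlfbp_infer,
    initialize_parameters,
    make_corrupted,
    make_training_pair,
    mse_loss,
    train,
)
from conftest import DESK_GRID, DESK_SPARSE_FACTOR


class TestMakeCorrupted:
    def test_full_size_shape_regardless_of_input_views(self, desk_geometry):
        phantom = EllipsePhantom([EllipseSpec(0, 0, 20, 14, 0.4, 1.0)], DESK_GRID)
        sino = analytic_fan_projection(phantom, desk_geometry)
        sparse = subsample_views(sino, DESK_SPARSE_FACTOR)
        corrupted = make_corrupted(sparse, desk_geometry, DESK_GRID)
        assert corrupted.values.shape == (
            desk_geometry.n_views,
            desk_geometry.n_channels,
        )
        assert corrupted.kind == "corrupted"

    def test_complete_input_near_identity(self, desk_geometry):
        """projection o FBP is close to identity on a smooth phantom."""
        phantom = EllipsePhantom(
            [EllipseSpec(0, 0, 22, 16, 0.2, 1.0), EllipseSpec(5, 4, 10, 8, 1.1, 0.5)],
            DESK_GRID,
        )
        sino = analytic_fan_projection(phantom, desk_geometry)
        corrupted = make_corrupted(
            subsample_views(sino, 1), desk_geometry, DESK_GRID
        )
        rel_rms = np.sqrt(((corrupted.values - sino.values) ** 2).mean()) / np.sqrt(
            (sino.values**2).mean()
        )
        assert rel_rms <= 0.05

    def test_zero_input_zero_output(self, desk_geometry):
        zeros = Sinogram(
            np.zeros((desk_geometry.n_views // DESK_SPARSE_FACTOR, desk_geometry.n_channels)),
            desk_geometry.view_angles[::DESK_SPARSE_FACTOR],
            desk_geometry,
            kind="sparse",
            factor=DESK_SPARSE_FACTOR,
            view_indices=np.arange(0, desk_geometry.n_views, DESK_SPARSE_FACTOR),
        )
        corrupted = make_corrupted(zeros, desk_geometry, DESK_GRID)
        assert not np.any(corrupted.values)


class TestMseLoss:
    def test_zero_for_identical(self):
        x = np.arange(6.0).reshape(2, 3)
        assert mse_loss(x, x) == 0.0

    def test_hand_example(self):
        assert mse_loss(np.array([0.0, 0.0]), np.array([1.0, 1.0]), m=1) == 1.0

    def test_quadratic_scaling(self):
        y = np.zeros(5)
        yhat = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        assert mse_loss(2 * yhat, y) == pytest.approx(4 * mse_loss(yhat, y))

    def test_batch_divisor(self):
        assert mse_loss(np.zeros(4), np.ones(4), m=2) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestDecayedLearningRate:
    def test_paper_schedule(self):
        cfg = TrainConfig()
        assert decayed_learning_rate(cfg, 0) == pytest.approx(1e-4)
        assert decayed_learning_rate(cfg, 19) == pytest.approx(1e-4)
        assert decayed_learning_rate(cfg, 20) == pytest.approx(1e-5)
        assert decayed_learning_rate(cfg, 40) == pytest.approx(1e-6)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            decayed_learning_rate(TrainConfig(), -1)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_monotone_non_increasing(self, step, gap):
        cfg = TrainConfig()
        assert decayed_learning_rate(cfg, step + gap) <= decayed_learning_rate(cfg, step)


class _OneLayerNet:
    """Duck-typed net exposing a single conv layer to initialize_parameters."""

    def __init__(self, layer):
        self._layers = [layer]

    def trainable_layers(self):
        return self._layers


class TestInitializeParameters:
    def test_unit_fan_std_one(self):
        class _Wide(Conv2D):
            fan_in = 1  # n_in = n_out = 1 -> std sqrt(2/2) = 1
            fan_out = 1

        wide = _Wide(1, 1, kernel=1)
        wide.w = np.zeros((1, 1, 1, 100_000))  # widen the draw, keep fans at 1
        training.initialize_parameters(_OneLayerNet(wide), seed=0)
        assert abs(wide.w.std() - 1.0) <= 0.02
        assert abs(wide.w.mean()) <= 3.0 / math.sqrt(100_000)

    def test_closed_form_std_for_conv(self):
        net = build_unet((16, 19), 8, 1)
        initialize_parameters(net, seed=4)
        conv = net.head[1].conv  # 3x3, 8 -> 8: fan_in 72, fan_out 72
        expected = math.sqrt(2.0 / (72 + 72))
        assert conv.w.std() == pytest.approx(expected, rel=0.1)
        assert not np.any(conv.b)

    def test_same_seed_identical(self):
        a = initialize_parameters(build_unet((16, 19), 4, 1), seed=9)
        b = initialize_parameters(build_unet((16, 19), 4, 1), seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestNadam:
    def test_matches_reference_formulas(self):
        cfg = TrainConfig(initial_learning_rate=0.01)
        p = np.array([1.0, -2.0])
        opt = NadamOptimizer([p], cfg)
        g = np.array([0.5, -1.0])
        opt.step([g], lr=0.01)
        b1, b2, eps = cfg.beta1, cfg.beta2, cfg.epsilon
        m = (1 - b1) * g
        v = (1 - b2) * g * g
        m_hat = b1 * m / (1 - b1) + (1 - b1) * g / (1 - b1)
        v_hat = v / (1 - b2)
        expected = np.array([1.0, -2.0]) - 0.01 * m_hat / (np.sqrt(v_hat) + eps)
        np.testing.assert_allclose(p, expected, rtol=1e-12)


@pytest.fixture(scope="module")
def tiny_pair(desk_geometry):
    phantom = EllipsePhantom(
        [EllipseSpec(0, 0, 20, 14, 0.4, 1.0), EllipseSpec(6, -4, 8, 6, 1.0, 0.6)],
        DESK_GRID,
    )
    sino = analytic_fan_projection(phantom, desk_geometry)
    return make_training_pair(
        subsample_views(sino, DESK_SPARSE_FACTOR),
        sino,
        desk_geometry,
        DESK_GRID,
    )


class TestTrain:
    def test_history_length_and_lr_schedule(self, tiny_pair, desk_geometry):
        net = initialize_parameters(
            build_unet((desk_geometry.n_views, desk_geometry.n_channels), 2, 1), seed=0
        )
        cfg = TrainConfig(
            initial_learning_rate=1e-3, decay_steps=2, outer_iterations=5, seed=0
        )
        _, history = train([tiny_pair], net, cfg)
        assert len(history) == 5
        rates = [h.learning_rate for h in history]
        assert rates == pytest.approx([1e-3, 1e-3, 1e-4, 1e-4, 1e-5])

    def test_reproducible_loss_history(self, tiny_pair, desk_geometry):
        shape = (desk_geometry.n_views, desk_geometry.n_channels)
        cfg = TrainConfig(initial_learning_rate=1e-3, outer_iterations=3, seed=5)
        histories = []
        for _ in range(2):
            net = initialize_parameters(build_unet(shape, 2, 1), seed=5)
            _, hist = train([tiny_pair], net, cfg)
            histories.append([h.loss for h in hist])
        assert histories[0] == histories[1]

    def test_single_pair_overfit(self, tiny_pair, desk_geometry):
        net = initialize_parameters(
            build_unet((desk_geometry.n_views, desk_geometry.n_channels), 8, 2), seed=2
        )
        cfg = TrainConfig(
            initial_learning_rate=2e-3,
            decay_steps=100,
            outer_iterations=200,
            seed=2,
        )
        _, history = train([tiny_pair], net, cfg)
        assert history[-1].loss < 0.1 * history[0].loss

    def test_empty_pairs_rejected(self, desk_geometry):
        net = build_unet((desk_geometry.n_views, desk_geometry.n_channels), 2, 1)
        with pytest.raises(ValueError):
            train([], net, TrainConfig())

    def test_non_finite_loss_aborts_with_diagnostic(
        self, tiny_pair, desk_geometry, monkeypatch
    ):
        net = initialize_parameters(
            build_unet((desk_geometry.n_views, desk_geometry.n_channels), 2, 1), seed=0
        )
        monkeypatch.setattr(training, "mse_loss", lambda *a, **k: float("nan"))
        with pytest.raises(FloatingPointError, match="epoch 0"):
            train([tiny_pair], net, TrainConfig(outer_iterations=1))


class TestDlfbpInfer:
    def test_shapes_and_tags(self, desk_geometry, trained_sparse_nets, desk_test_items):
        item = desk_test_items[0]
        image, restored = dlfbp_infer(
            item["incomplete"]["sparse"],
            trained_sparse_nets["strided_conv"],
            desk_geometry,
            DESK_GRID,
        )
        assert image.values.shape == (DESK_GRID, DESK_GRID)
        assert restored.values.shape == (
            desk_geometry.n_views,
            desk_geometry.n_channels,
        )
        assert restored.kind == "restored"

    def test_identity_network_reduces_to_fbp_of_corrupted(
        self, desk_geometry, desk_test_items
    ):
        item = desk_test_items[0]
        incomplete = item["incomplete"]["sparse"]
        identity = build_unet(
            (desk_geometry.n_views, desk_geometry.n_channels), 2, 1
        )  # zero residual path
        image, restored = dlfbp_infer(
            incomplete, identity, desk_geometry, DESK_GRID, rescale="corrupted_stats"
        )
        corrupted = make_corrupted(incomplete, desk_geometry, DESK_GRID)
        baseline = fbp_reconstruct(corrupted, desk_geometry, DESK_GRID)
        np.testing.assert_allclose(restored.values, corrupted.values, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(image.values, baseline.values, atol=1e-5)

    def test_repeat_inference_identical(
        self, desk_geometry, trained_sparse_nets, desk_test_items
    ):
        item = desk_test_items[1]
        net = trained_sparse_nets["strided_conv"]
        img1, res1 = dlfbp_infer(item["incomplete"]["sparse"], net, desk_geometry, DESK_GRID)
        img2, res2 = dlfbp_infer(item["incomplete"]["sparse"], net, desk_geometry, DESK_GRID)
        np.testing.assert_array_equal(img1.values, img2.values)
        np.testing.assert_array_equal(res1.values, res2.values)

    def test_unknown_rescale_rejected(self, desk_geometry, desk_test_items):
        net = build_unet((desk_geometry.n_views, desk_geometry.n_channels), 2, 1)
        with pytest.raises(ValueError, match="rescale"):
            dlfbp_infer(
                desk_test_items[0]["incomplete"]["sparse"],
                net,
                desk_geometry,
                DESK_GRID,
                rescale="target_stats",
            )


def test_end_to_end_improvement_both_conditions(
    desk_geometry, trained_sparse_nets, trained_limited_net, desk_test_items
):
    """DLFBP strictly beats direct FBP on held-out phantoms, both conditions."""
    mask = support_mask(DESK_GRID)
    nets = {"sparse": trained_sparse_nets["strided_conv"], "limited": trained_limited_net}
    for case, net in nets.items():
        fbp_scores, dl_scores = [], []
        for item in desk_test_items:
            incomplete = item["incomplete"][case]
            truth = item["phantom_image"]
            direct = fbp_reconstruct(
                embed_incomplete(incomplete), desk_geometry, DESK_GRID
            )
            dl_img, _ = dlfbp_infer(incomplete, net, desk_geometry, DESK_GRID)
            fbp_scores.append(psnr(truth, direct.values, mask=mask))
            dl_scores.append(psnr(truth, dl_img.values, mask=mask))
        assert np.mean(dl_scores) > np.mean(fbp_scores), case
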