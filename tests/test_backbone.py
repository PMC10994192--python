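"""Backbone construction and pretraining: shapes, schedules, determinism."""

import numpy as np
import pandas as pd
import pytest

from umsrep import nn
from umsrep.backbone import (DEFAULT_NOISE_LADDER, BackboneModel, PretrainConfig,
                             _EarlyStopper, build_cdae, build_supervised_backbone,
                             evaluate_denoising, load_backbone, pretrain_denoising,
                             pretrain_supervised, save_backbone)
from umsrep.image_io import ModalitySource
from umsrep.phantom_data import NoiseSpec, PhantomConfig, generate_phantoms


def _tiny_source(style="xray_like", n=40, size=32, seed=0):
    cfg = PhantomConfig(image_size=size, style=style, n_samples=n,
                        abnormal_fraction=0.5 if style == "xray_like" else None,
                        seed=seed)
    return ModalitySource.from_samples(generate_phantoms(cfg))


class TestConstruction:
    def test_cdae_preserves_input_shape(self):
        model = build_cdae(widths=(4, 4, 8, 8), input_size=64)
        x = np.random.default_rng(0).random((2, 1, 64, 64)).astype(np.float32)
        assert model.net.forward(x).shape == (2, 1, 64, 64)

    def test_cdae_bottleneck_is_four_by_four_at_64(self):
        model = build_cdae(widths=(4, 4, 8, 8), input_size=64)
        x = np.zeros((1, 1, 64, 64), np.float32)
        assert model.encoder().forward(x).shape == (1, 8, 4, 4)

    def test_cdae_rejects_indivisible_input(self):
        with pytest.raises(ValueError, match="divisible"):
            build_cdae(input_size=60)

    def test_supervised_feature_map_keeps_spatial_size(self):
        model = build_supervised_backbone(widths=(4, 4, 4, 4, 4, 4), n_classes=3,
                                          input_size=64, fc_width=8)
        x = np.zeros((1, 1, 64, 64), np.float32)
        assert model.encoder().forward(x).shape == (1, 4, 64, 64)

    def test_supervised_softmax_sums_to_one(self, rng):
        model = build_supervised_backbone(widths=(4, 4, 4, 4, 4, 4), n_classes=3,
                                          input_size=32, fc_width=8)
        y = model.net.forward(rng.random((3, 1, 32, 32)).astype(np.float32))
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_supervised_final_layer_parameter_formula(self):
        model = build_supervised_backbone(widths=(4, 4, 4, 4, 4, 4), n_classes=3,
                                          input_size=32, fc_width=7)
        final_fc = [l for l in model.arch.layers if l.kind == "fc"][-1]
        assert final_fc.n_parameters == (7 + 1) * 3

    def test_dilation_on_last_three_convs(self):
        model = build_supervised_backbone(widths=(4,) * 6, n_classes=2, input_size=32)
        dils = [l.dilation for l in model.arch.layers if l.kind == "conv2d"]
        assert dils == [1, 1, 1, 2, 2, 2]


class TestEarlyStopping:
    def test_stops_after_exactly_patience_bad_epochs(self):
        net = nn.Sequential([nn.Dense(2, 2)]).initialize(np.random.default_rng(0))
        opt = nn.Adam(lr=1e-3)
        stopper = _EarlyStopper(plateau_factor=0.5, plateau_patience=2,
                                early_stop_patience=4)
        stopper.update(1.0, net, opt)
        stops = [stopper.update(2.0, net, opt) for _ in range(4)]
        assert stops == [False, False, False, True]

    def test_lr_halves_on_plateau(self):
        net = nn.Sequential([nn.Dense(2, 2)]).initialize(np.random.default_rng(0))
        opt = nn.Adam(lr=1e-3)
        stopper = _EarlyStopper(plateau_factor=0.5, plateau_patience=2,
                                early_stop_patience=10)
        stopper.update(1.0, net, opt)
        for _ in range(4):
            stopper.update(2.0, net, opt)
        assert opt.lr == pytest.approx(2.5e-4)      # two plateau reductions

    def test_best_state_restored(self):
        net = nn.Sequential([nn.Dense(2, 2)]).initialize(np.random.default_rng(0))
        opt = nn.Adam(lr=1e-3)
        stopper = _EarlyStopper(0.5, 2, 4)
        stopper.update(1.0, net, opt)
        best = net.state_hash()
        net.parameters()[0][...] += 1.0
        stopper.update(2.0, net, opt)
        stopper.restore(net)
        assert net.state_hash() == best


class TestPretraining:
    def test_denoising_is_deterministic_across_runs(self):
        source = _tiny_source()
        histories = []
        for _ in range(2):
            model = build_cdae(widths=(4, 4, 8, 8), input_size=32, seed=5)
            _, hist = pretrain_denoising(model, source,
                                         noise_specs=[NoiseSpec("gaussian", 20)],
                                         cfg=PretrainConfig(max_epochs=2, seed=5))
            histories.append(hist)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_theta_changes_after_training(self):
        source = _tiny_source()
        model = build_cdae(widths=(4, 4, 8, 8), input_size=32, seed=0)
        before = model.net.state_hash()
        pretrain_denoising(model, source, noise_specs=[NoiseSpec("gaussian", 20)],
                           cfg=PretrainConfig(max_epochs=1, seed=0))
        assert model.net.state_hash() != before

    def test_empty_train_split_rejected(self):
        source = _tiny_source()
        source.frame["split"] = "test"
        model = build_cdae(widths=(4, 4, 8, 8), input_size=32)
        with pytest.raises(ValueError, match="empty train split"):
            pretrain_denoising(model, source, cfg=PretrainConfig(max_epochs=1))

    def test_supervised_loss_matches_metric_cce(self):
        from umsrep.backbone import classify, onehot
        from umsrep.nn.losses import cce_vg

        source = _tiny_source(style="doppler_like")
        model = build_supervised_backbone(widths=(4,) * 6, n_classes=3,
                                          input_size=32, fc_width=8, seed=0)
        model, _ = pretrain_supervised(model, source,
                                       cfg=PretrainConfig(loss="cce", optimizer="adam",
                                                          max_epochs=1, seed=0))
        probs = classify(model, source.images_for("val"))
        t = onehot(source.labels_for("val"), model.classes)
        batch_value, _ = cce_vg(probs, t)
        from umsrep.metrics_losses import cce_loss

        per = [cce_loss(ti, yi) for ti, yi in zip(t, probs)]
        assert batch_value == pytest.approx(np.mean(per), rel=1e-6)

    def test_validation_loss_improves_on_small_run(self, small_cdae_setup):
        hist = small_cdae_setup["history"]
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]


class TestEvaluateDenoising:
    def test_table_has_one_row_per_noise_spec(self, small_cdae_setup):
        table = evaluate_denoising(small_cdae_setup["model"],
                                   small_cdae_setup["source"],
                                   DEFAULT_NOISE_LADDER, seed=0)
        assert len(table) == len(DEFAULT_NOISE_LADDER)
        assert list(table.columns) == ["noise", "psnr", "ssim", "ms_ssim"]

    def test_raw_input_psnr_decreases_with_sigma(self, small_cdae_setup):
        specs = [NoiseSpec("gaussian", s) for s in (10, 20, 30, 40, 50)]
        table = evaluate_denoising(small_cdae_setup["model"],
                                   small_cdae_setup["source"], specs, seed=0,
                                   include_noisy_input=True)
        noisy = table["psnr_noisy"].tolist()
        assert all(a > b for a, b in zip(noisy, noisy[1:]))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, small_cdae_setup):
        model = small_cdae_setup["model"]
        save_backbone(model, tmp_path / "ckpt")
        loaded = load_backbone(tmp_path / "ckpt")
        x = np.random.default_rng(0).random((2, 32, 32)).astype(np.float32)
        np.testing.assert_allclose(model.net.forward(model.prepare(x)),
                                   loaded.net.forward(loaded.prepare(x)), atol=1e-6)
        assert loaded.kind == "cdae"
        assert loaded.encoder_cut_point == model.encoder_cut_point
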