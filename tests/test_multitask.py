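"""Head attachment, alternating schedules, and the three fine-tuning strategies."""

import numpy as np
import pytest

from umsrep.arch import count_parameters
from umsrep.backbone import build_cdae, build_supervised_backbone
from umsrep.multitask import (FinetuneConfig, FinetuneError, MultiTaskModel,
                              TaskData, TaskSpec, alternating_schedule,
                              attach_classification_head, attach_segmentation_head,
                              finetune, joint_theta_src_gradient, predict)


def _model(kind="cdae", size=32, seed=0):
    if kind == "cdae":
        bb = build_cdae(widths=(4, 4, 8, 8), input_size=size, seed=seed)
    else:
        bb = build_supervised_backbone(widths=(4,) * 6, n_classes=3,
                                       input_size=size, fc_width=8, seed=seed)
    bb.normalizer.mean_ = 0.3
    return MultiTaskModel(backbone=bb)


def _data(mtm, n=12, seed=0):
    rng = np.random.default_rng(seed)
    size = mtm.backbone.input_size
    out = {}
    for name, head in mtm.heads.items():
        x = rng.random((n, size, size)).astype(np.float32)
        if head.task.kind == "segmentation":
            t = (rng.random((n, size, size)) > 0.5).astype(np.uint8)
        else:
            t = rng.choice(head.task.label_space, size=n)
        out[name] = TaskData(images=x, targets=t)
    return out


class TestAttachment:
    @pytest.mark.parametrize("kind", ["cdae", "supervised"])
    def test_segmentation_output_matches_input_shape(self, kind, rng):
        mtm = _model(kind)
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        y = mtm.forward("seg", rng.random((2, 32, 32)).astype(np.float32))
        assert y.shape == (2, 1, 32, 32)
        assert 0.0 < y.min() and y.max() < 1.0

    def test_classification_probabilities_sum_to_one(self, rng):
        mtm = _model("cdae")
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"], fc_width=6))
        y = mtm.forward("cls", rng.random((3, 32, 32)).astype(np.float32))
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)

    def test_classification_head_parameter_formula(self):
        mtm = _model("cdae")
        head = attach_classification_head(
            mtm, TaskSpec(name="cls", kind="classification",
                          label_space=["a", "b", "c"], fc_width=10))
        c = mtm.backbone.encoder_channels
        expected = (c + 1) * 10 + (10 + 1) * 3
        assert count_parameters(head.arch) == expected
        assert head.net.n_parameters() == expected

    def test_segmentation_head_count_matches_engine(self):
        mtm = _model("supervised")
        head = attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        assert count_parameters(head.arch) == head.net.n_parameters()

    def test_cdae_segmentation_head_reuses_decoder_weights(self):
        mtm = _model("cdae")
        head = attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        bb = mtm.backbone
        dec_first = bb.net.layers[bb.encoder_cut_point + 1 + 1]  # first decoder conv
        np.testing.assert_array_equal(head.net.layers[1].params["W"],
                                      dec_first.params["W"])
        assert head.net.layers[1] is not dec_first   # copied, not aliased

    def test_two_heads_share_one_theta_src(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"]))
        enc1 = mtm.encoder()
        enc2 = mtm.encoder()
        assert all(p1 is p2 for p1, p2 in zip(enc1.parameters(), enc2.parameters()))

    def test_kind_mismatch_rejected(self):
        mtm = _model("cdae")
        with pytest.raises(FinetuneError):
            attach_segmentation_head(mtm, TaskSpec(name="x", kind="classification",
                                                   label_space=["a", "b"]))


class TestAlternatingSchedule:
    def test_unit_ratios_interleave(self):
        assert alternating_schedule({"A": 1, "B": 1}, 2) == ["A", "B", "A", "B"]

    def test_two_to_one_ratio(self):
        assert alternating_schedule({"A": 2, "B": 1}, 2) == ["A", "A", "B", "A", "A", "B"]

    def test_single_task(self):
        assert alternating_schedule({"A": 3}, 2) == ["A"] * 6

    def test_zero_ratio_rejected(self):
        with pytest.raises(FinetuneError):
            alternating_schedule({"A": 0}, 1)

    def test_length_is_cycles_times_ratio_sum(self):
        sched = alternating_schedule({"A": 2, "B": 3, "C": 1}, 4)
        assert len(sched) == 4 * 6
        assert sched.count("B") == 12


class TestStrategies:
    def test_independent_leaves_theta_src_bit_identical(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"]))
        before = mtm.encoder().state_hash()
        finetune(mtm, FinetuneConfig(strategy="independent", epochs=2,
                                     batch_size=4, seed=0), _data(mtm))
        assert mtm.encoder().state_hash() == before

    def test_alternating_updates_theta_src(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        before = mtm.encoder().state_hash()
        finetune(mtm, FinetuneConfig(strategy="alternating", epochs=1,
                                     batch_size=4, seed=0,
                                     batch_ratios={"seg": 1}), _data(mtm))
        assert mtm.encoder().state_hash() != before

    def test_alternating_history_counts_follow_ratios(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"]))
        hist = finetune(mtm, FinetuneConfig(strategy="alternating", epochs=1,
                                            batch_size=4, seed=0, cycles=5,
                                            batch_ratios={"seg": 2, "cls": 1}),
                        _data(mtm))
        assert len(hist["seg"]) == 10 and len(hist["cls"]) == 5

    def test_joint_zero_weight_head_receives_no_update(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"]))
        before = mtm.head("cls").net.state_hash()
        finetune(mtm, FinetuneConfig(strategy="joint", epochs=1, batch_size=4,
                                     seed=0, task_weights={"seg": 1.0, "cls": 0.0}),
                 _data(mtm))
        assert mtm.head("cls").net.state_hash() == before
        assert mtm.encoder().state_hash()  # encoder still trained by task 1

    def test_joint_gradient_is_weighted_sum_by_finite_differences(self):
        """theta_src gradient under the joint loss vs a central-difference oracle."""
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="segA", kind="segmentation"),
                                 seed=1)
        attach_segmentation_head(mtm, TaskSpec(name="segB", kind="segmentation"),
                                 seed=2)
        mtm.backbone.net.astype(np.float64)
        for head in mtm.heads.values():
            head.net.astype(np.float64)
        rng = np.random.default_rng(0)
        weights = {"segA": 0.7, "segB": 1.3}
        batches = {}
        for name in mtm.heads:
            x = rng.random((3, 1, 32, 32))
            t = (rng.random((3, 1, 32, 32)) > 0.5).astype(np.float64)
            batches[name] = (x, t)
        grads = joint_theta_src_gradient(mtm, batches, weights)

        from umsrep.multitask import _loss_vg

        def joint_loss():
            total = 0.0
            enc = mtm.encoder()
            for name, (x, t) in batches.items():
                f = enc.forward(x, training=True)
                y = mtm.head(name).net.forward(f, training=True)
                loss, _ = _loss_vg(mtm.head(name).task, y, t)
                total += weights[name] * loss
            return total

        params = mtm.encoder().parameters()
        h = 1e-6
        check = np.random.default_rng(2)
        for _ in range(15):
            pi = int(check.integers(len(params)))
            idx = tuple(int(check.integers(s)) for s in params[pi].shape)
            orig = params[pi][idx]
            params[pi][idx] = orig + h
            lp = joint_loss()
            params[pi][idx] = orig - h
            lm = joint_loss()
            params[pi][idx] = orig
            fd = (lp - lm) / (2 * h)
            an = grads[pi][idx]
            assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an), 1e-6)

    def test_single_task_joint_equals_alternating_trajectory(self):
        """With one task, weight 1 and matching Adam settings, the two
        strategies walk the identical parameter trajectory."""
        states = {}
        for strategy in ("joint", "alternating"):
            mtm = _model("cdae", seed=4)
            task = TaskSpec(name="seg", kind="segmentation", optimizer="adam",
                            optimizer_kwargs={"lr": 1e-3})
            attach_segmentation_head(mtm, task, seed=4)
            cfg = FinetuneConfig(strategy=strategy, epochs=2, batch_size=4, seed=4,
                                 task_weights={"seg": 1.0}, batch_ratios={"seg": 1},
                                 joint_lr=1e-3,
                                 cycles=6 if strategy == "alternating" else None)
            finetune(mtm, cfg, _data(mtm, seed=4))
            states[strategy] = (mtm.encoder().state_hash(),
                                mtm.head("seg").net.state_hash())
        assert states["joint"] == states["alternating"]

    def test_missing_configuration_rejected(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        with pytest.raises(FinetuneError):
            finetune(mtm, FinetuneConfig(strategy="joint", task_weights={"other": 1.0}),
                     _data(mtm))
        with pytest.raises(FinetuneError):
            finetune(mtm, FinetuneConfig(strategy="alternating",
                                         batch_ratios={"other": 1}), _data(mtm))

    def test_missing_task_data_rejected(self):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        with pytest.raises(FinetuneError, match="no data"):
            finetune(mtm, FinetuneConfig(strategy="independent"), {})


class TestPredict:
    def test_probability_vector_sums_to_one(self, rng):
        mtm = _model("cdae")
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b", "c"]))
        pred = predict(mtm, "cls", rng.random((32, 32)).astype(np.float32))
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert pred.label in ("a", "b", "c")

    def test_threshold_maps_ties_to_foreground(self):
        pmap = np.full((4, 4), 0.5)
        mask = (pmap >= 0.5).astype(np.uint8)
        assert mask.all()    # the 0.5 tie rule: foreground

    def test_uniform_high_probability_map_gives_all_ones(self, rng):
        mtm = _model("cdae")
        attach_segmentation_head(mtm, TaskSpec(name="seg", kind="segmentation"))
        head = mtm.head("seg")
        # force the final conv to a large positive bias -> sigmoid ~ 0.88 > 0.5
        final_conv = head.net.layers[-2]
        final_conv.params["W"][...] = 0.0
        final_conv.params["b"][...] = 2.0
        pred = predict(mtm, "seg", rng.random((32, 32)).astype(np.float32))
        assert pred.mask.all()

    def test_inference_is_deterministic_despite_dropout(self, rng):
        mtm = _model("cdae")
        attach_classification_head(mtm, TaskSpec(name="cls", kind="classification",
                                                 label_space=["a", "b"]))
        img = rng.random((32, 32)).astype(np.float32)
        p1 = predict(mtm, "cls", img).probabilities
        p2 = predict(mtm, "cls", img).probabilities
        np.testing.assert_array_equal(p1, p2)

    def test_unknown_task_rejected(self):
        mtm = _model("cdae")
        with pytest.raises(FinetuneError, match="unknown task"):
            predict(mtm, "ghost", np.zeros((32, 32), np.float32))
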