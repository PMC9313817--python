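"""Losses, weight transfer, fine-tuning and prediction."""
import numpy as np
import pytest

from muscleseg import (
    BinaryMask,
    TrainConfig,
    bce_loss,
    combined_loss,
    dice_loss,
    dsc,
    fine_tune,
    predict,
    transfer_weights,
)
from muscleseg.nn import NetConfig, SegmentationNet
from muscleseg.preprocess import AugmentConfig
from muscleseg.training import bce_dice_logits
from muscleseg.weights import NamedWeights

TINY = NetConfig(width=4)


def target_shapes(cfg=TINY):
    return {k: p.value.shape for k, p in SegmentationNet(cfg, 0).named_parameters().items()}


class TestLosses:
    def test_bce_half_probability_is_ln2(self):
        p = np.full((8, 8), 0.5)
        y = (np.random.default_rng(0).random((8, 8)) < 0.5).astype(float)
        assert bce_loss(p, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_perfect_prediction_near_zero(self):
        y = np.zeros((8, 8))
        y[2:5, 2:5] = 1
        assert bce_loss(y, y) < 1e-5

    def test_bce_matches_pixel_sum_on_random_case(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, (4, 4))
        y = (rng.random((4, 4)) < 0.5).astype(float)
        manual = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_loss(p, y) == pytest.approx(manual, rel=1e-10)

    def test_dice_identical_and_disjoint(self):
        a = np.zeros((6, 6))
        a[:3] = 1
        b = np.zeros((6, 6))
        b[3:] = 1
        assert dice_loss(a, a) == pytest.approx(0.0, abs=1e-6)
        assert dice_loss(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_dice_half_overlap_equal_area(self):
        a = np.zeros((4, 4))
        a[:, :2] = 1  # 8 px
        b = np.zeros((4, 4))
        b[:, 1:3] = 1  # 8 px, overlap 4 -> 1 - 2*4/16 = 0.5
        assert dice_loss(a, b) == pytest.approx(0.5, abs=1e-6)

    def test_combined_is_batch_mean_of_per_sample_sums(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, (2, 3, 3))
        y = (rng.random((2, 3, 3)) < 0.5).astype(float)
        expected = np.mean(
            [bce_loss(p[i], y[i]) + dice_loss(p[i], y[i]) for i in range(2)]
        )
        assert combined_loss(p, y) == pytest.approx(expected, rel=1e-12)
        assert combined_loss(y, y) < 1e-5

    def test_logit_loss_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(2, 1, 4, 4))
        y = (rng.random((2, 4, 4)) < 0.4).astype(float)
        loss, dz = bce_dice_logits(z, y)
        eps = 1e-6
        for idx in [(0, 0, 1, 2), (1, 0, 3, 0)]:
            zp = z.copy()
            zp[idx] += eps
            zm = z.copy()
            zm[idx] -= eps
            num = (bce_dice_logits(zp, y)[0] - bce_dice_logits(zm, y)[0]) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-5)


class TestTransfer:
    def test_identity_transfer_matches_everything(self):
        shapes = target_shapes()
        src = NamedWeights(
            entries=SegmentationNet(TINY, seed=3).state_dict(), source_task="segmentation"
        )
        init, rep = transfer_weights(src, shapes, seed=0)
        assert sorted(rep.matched) == sorted(shapes)
        assert rep.unmatched_target == []
        for k in shapes:
            assert np.array_equal(init.entries[k], src.entries[k])

    def test_empty_source_randomizes_everything(self):
        shapes = target_shapes()
        init, rep = transfer_weights(None, shapes, seed=0)
        assert rep.matched == []
        assert sorted(rep.unmatched_target) == sorted(shapes)
        init2, _ = transfer_weights(None, shapes, seed=0)
        assert all(np.array_equal(init.entries[k], init2.entries[k]) for k in shapes)
        init3, _ = transfer_weights(None, shapes, seed=1)
        assert any(not np.array_equal(init.entries[k], init3.entries[k]) for k in shapes)

    def test_encoder_only_source_matches_enumerated_names(self):
        shapes = target_shapes()
        full = SegmentationNet(TINY, seed=3).state_dict()
        enc = NamedWeights(
            entries={k: v for k, v in full.items() if k.startswith("encoder.")},
            source_task="jigsaw",
        )
        init, rep = transfer_weights(enc, shapes, seed=0)
        expected = sorted(k for k in shapes if k.startswith("encoder."))
        assert sorted(rep.matched) == expected
        assert sorted(rep.unmatched_target) == sorted(
            k for k in shapes if not k.startswith("encoder.")
        )

    def test_shape_mismatch_recorded_not_fatal(self):
        shapes = target_shapes()
        bad = NamedWeights(
            entries={"head.weight": np.zeros((2, 4, 1, 1))}, source_task="x"
        )
        init, rep = transfer_weights(bad, shapes, seed=0)
        assert "head.weight" in rep.unmatched_target
        assert "head.weight" in rep.unmatched_source

    def test_union_covers_target_exactly_once(self):
        shapes = target_shapes()
        full = SegmentationNet(TINY, seed=3).state_dict()
        enc = NamedWeights(
            entries={k: v for k, v in full.items() if k.startswith("encoder.")},
            source_task="jigsaw",
        )
        _, rep = transfer_weights(enc, shapes, seed=0)
        assert sorted(rep.matched + rep.unmatched_target) == sorted(shapes)


@pytest.fixture(scope="module")
def tiny_data(small_cohort_module=None):
    from muscleseg import PhantomParams, generate_phantom, to_model_input, window_level

    params = PhantomParams(cohort_size=12, image_side=48, spacing_mm=8.0)
    cohort = generate_phantom(params, seed=55)
    inputs = [to_model_input(window_level(ct), provenance=ct.slice_id) for ct, _, _ in cohort]
    data = [(inp, m) for inp, (_, m, _) in zip(inputs, cohort)]
    return cohort, inputs, data


class TestFineTune:
    def test_run_completes_with_histories_and_lr_rule(self, tiny_data):
        _, _, data = tiny_data
        cfg = TrainConfig(net=TINY, max_epochs=5, patience=5)
        init, rep = transfer_weights(None, target_shapes(), seed=0)
        run = fine_tune(init, rep, data[:5], data[5:8], cfg, seed=1)
        assert rep.learning_rate == cfg.lr_scratch
        assert len(run.val_loss) == len(run.train_loss) > 0
        assert run.best_epoch >= 0
        src = NamedWeights(entries=SegmentationNet(TINY, 9).state_dict(), source_task="s")
        init2, rep2 = transfer_weights(src, target_shapes(), seed=0)
        fine_tune(init2, rep2, data[:5], data[5:8], cfg, seed=1)
        assert rep2.learning_rate == cfg.lr_transfer

    def test_same_seed_identical_histories(self, tiny_data):
        _, _, data = tiny_data
        cfg = TrainConfig(net=TINY, max_epochs=4, patience=4)
        init, rep = transfer_weights(None, target_shapes(), seed=2)
        a = fine_tune(init, rep, data[:4], data[5:8], cfg, seed=3)
        b = fine_tune(init, rep, data[:4], data[5:8], cfg, seed=3)
        assert a.train_loss == b.train_loss
        assert a.val_loss == b.val_loss

    def test_checkpoint_is_min_validation_loss(self, tiny_data):
        _, _, data = tiny_data
        cfg = TrainConfig(net=TINY, max_epochs=8, patience=8)
        init, rep = transfer_weights(None, target_shapes(), seed=0)
        run = fine_tune(init, rep, data[:5], data[5:8], cfg, seed=4)
        assert run.val_loss[run.best_epoch] == min(run.val_loss)

    def test_single_step_decreases_loss_on_fixed_batch(self, tiny_data):
        _, _, data = tiny_data
        cfg = TrainConfig(
            net=TINY, max_epochs=1, patience=1, use_augmentation=False,
            lr_scratch=1e-4,
        )
        init, rep = transfer_weights(None, target_shapes(), seed=0)
        xs = np.stack([inp.channels for inp, _ in data[:4]])
        ys = np.stack([m.labels.astype(float) for _, m in data[:4]])
        net = SegmentationNet(TINY, 0)
        net.load_state_dict(init.entries)
        before, _ = bce_dice_logits(net(xs), ys)
        run = fine_tune(init, rep, data[:4], data[:4], cfg, seed=0)
        net.load_state_dict(run.checkpoint.entries)
        after, _ = bce_dice_logits(net(xs), ys)
        assert after < before


class TestPredict:
    def test_saturated_logits_full_and_empty(self, tiny_data):
        cohort, inputs, _ = tiny_data
        spacing = cohort[0][0].spacing
        state = SegmentationNet(TINY, 0).state_dict()
        for fill, expect in [(50.0, 1), (-50.0, 0)]:
            st = {k: np.zeros_like(v) for k, v in state.items()}
            st["head.bias"] = np.array([fill])
            ck = NamedWeights(entries=st, source_task="x")
            out = predict(ck, inputs[0], TINY, spacing)
            assert np.all(out.labels == expect)

    def test_zero_logit_is_foreground_by_convention(self, tiny_data):
        cohort, inputs, _ = tiny_data
        state = {k: np.zeros_like(v) for k, v in SegmentationNet(TINY, 0).state_dict().items()}
        ck = NamedWeights(entries=state, source_task="x")
        out = predict(ck, inputs[0], TINY, cohort[0][0].spacing)
        assert np.all(out.labels == 1)  # sigmoid(0) = 0.5 >= 0.5
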