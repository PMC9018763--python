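import numpy as np
import pytest

from dentseg.nets import (
    Adam,
    EarlyStopper,
    HeadSpec,
    NetConfig,
    TrainConfig,
    build_segnet,
    class_from_fdi,
    compute_losses,
    fdi_from_class,
    load_checkpoint,
    predict_patchwise,
    save_checkpoint,
    train_model,
)
from dentseg.nets.losses import losses_and_logit_grads
from dentseg.io_core import Volume

MASK_HEAD = (HeadSpec("mask", 1, "sigmoid"),)


def tiny_cfg(**kw):
    defaults = dict(in_channels=1, levels=2, base_channels=2, patch=(8, 8, 8), heads=MASK_HEAD)
    defaults.update(kw)
    return NetConfig(**defaults)


class TestNetConfig:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(1, 3, 2, (10, 8, 8), MASK_HEAD)

    def test_duplicate_head_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            NetConfig(1, 2, 2, (8, 8, 8), (HeadSpec("m", 1, "sigmoid"), HeadSpec("m", 3, "linear")))

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError):
            HeadSpec("m", 1, "tanh")


class TestBuildSegnet:
    def test_sigmoid_head_shape_and_range(self, rng):
        pred = build_segnet(tiny_cfg(), seed=0)
        out = pred.predict(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert out["mask"].shape == (1, 8, 8, 8)
        assert np.all((out["mask"] >= 0) & (out["mask"] <= 1))

    def test_multihead_offset_and_mask(self, rng):
        cfg = tiny_cfg(heads=(HeadSpec("offset", 3, "linear"), HeadSpec("mask", 1, "sigmoid")))
        out = build_segnet(cfg, 0).predict(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert out["offset"].shape == (3, 8, 8, 8)
        assert out["mask"].shape == (1, 8, 8, 8)

    def test_classifier_branch_emits_32_logits(self, rng):
        cfg = tiny_cfg(n_classes=32)
        out = build_segnet(cfg, 0).predict(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert out["class_logits"].shape == (32,)

    def test_softmax_head_sums_to_one(self, rng):
        cfg = tiny_cfg(heads=(HeadSpec("bones", 3, "softmax"),))
        pred = build_segnet(cfg, 0)
        for _ in range(5):
            out = pred.predict(rng.standard_normal((1, 8, 8, 8)).astype(np.float32) * 3)
            np.testing.assert_allclose(out["bones"].sum(axis=0), 1.0, atol=1e-5)
            assert np.all(out["bones"] >= 0)

    def test_seeded_init_is_deterministic(self, rng):
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        a = build_segnet(tiny_cfg(), seed=5).predict(x)
        b = build_segnet(tiny_cfg(), seed=5).predict(x)
        np.testing.assert_array_equal(a["mask"], b["mask"])

    def test_wrong_input_shape_rejected(self, rng):
        pred = build_segnet(tiny_cfg(), 0)
        with pytest.raises(ValueError):
            pred.predict(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))


class TestFdiTable:
    def test_class_fdi_bijection_endpoints(self):
        assert fdi_from_class(0) == 11
        assert fdi_from_class(31) == 48
        for i in range(32):
            assert class_from_fdi(fdi_from_class(i)) == i


class TestLosses:
    def test_perfect_regression_loss_is_zero(self, rng):
        cfg = tiny_cfg(heads=(HeadSpec("b", 1, "linear"),))
        t = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
        out = compute_losses({"b": t.copy()}, {"b": t}, cfg)
        assert out["b"] == 0.0 and out["total"] == 0.0

    def test_bce_at_half_is_ln2(self, rng):
        cfg = tiny_cfg()
        t = (rng.random((1, 4, 4, 4)) > 0.5).astype(np.float32)
        out = compute_losses({"mask": np.full_like(t, 0.5)}, {"mask": t}, cfg)
        assert out["mask"] == pytest.approx(np.log(2.0), rel=1e-6)

    def test_masked_offset_loss_with_empty_foreground_is_zero(self, rng):
        cfg = tiny_cfg(heads=(HeadSpec("offset", 3, "linear", masked=True),))
        p = rng.standard_normal((3, 4, 4, 4)).astype(np.float32)
        out = compute_losses({"offset": p}, {"offset": np.zeros_like(p)}, cfg,
                             mask=np.zeros((4, 4, 4), dtype=bool))
        assert out["offset"] == 0.0 and np.isfinite(out["total"])

    def test_shape_mismatch_rejected(self, rng):
        cfg = tiny_cfg()
        with pytest.raises(ValueError):
            compute_losses({"mask": np.zeros((1, 4, 4, 4))}, {"mask": np.zeros((1, 5, 4, 4))}, cfg)

    def test_loss_weights_scale_total(self, rng):
        cfg = tiny_cfg(heads=(HeadSpec("b", 1, "linear"),))
        p = np.ones((1, 2, 2, 2), dtype=np.float32)
        t = np.zeros_like(p)
        base = compute_losses({"b": p}, {"b": t}, cfg)["total"]
        scaled = compute_losses({"b": p}, {"b": t}, cfg, weights={"b": 2.5})["total"]
        assert scaled == pytest.approx(2.5 * base)

    def test_logit_space_gradients_match_numeric(self, rng):
        """Backprop through the whole net agrees with finite differences."""
        cfg = NetConfig(
            2, 2, 3, (8, 8, 8),
            (HeadSpec("mask", 1, "sigmoid"), HeadSpec("off", 3, "linear", masked=True)),
            n_classes=4,
        )
        net = build_segnet(cfg, seed=1).net
        x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        tgt = {
            "mask": (rng.random((1, 8, 8, 8)) > 0.5).astype(np.float32),
            "off": rng.standard_normal((3, 8, 8, 8)).astype(np.float32),
        }
        mask = rng.random((8, 8, 8)) > 0.6

        def total():
            hr, cl, _ = net.forward(x)
            return losses_and_logit_grads(hr, cl, tgt, cfg, mask=mask, class_target=2)[0]["total"]

        hr, cl, cache = net.forward(x, keep_cache=True)
        _, dh, dc = losses_and_logit_grads(hr, cl, tgt, cfg, mask=mask, class_target=2)
        grads = {k: np.zeros_like(v) for k, v in net.params.items()}
        net.backward(dh, dc, cache, grads)
        for name in ["enc0a.w", "up0.w", "dec0.w", "head_mask.w", "fc1.b"]:
            p = net.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, old = 1e-3, p[idx]
            p[idx] = old + eps
            lp = total()
            p[idx] = old - eps
            lm = total()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[name][idx]
            assert abs(num - ana) <= 3e-2 * max(1.0, abs(num) + abs(ana)), name


def _toy_dataset(rng, n=3):
    samples = []
    for _ in range(n):
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        samples.append({"input": x, "targets": {"mask": (x > 0).astype(np.float32)}})
    return samples


class TestEarlyStopping:
    def test_plateau_trace_stops_after_five_stale_epochs(self):
        """1.0 then constant 0.9: epochs 3-7 are non-improving -> stop at 7."""
        stopper = EarlyStopper(patience=5, tolerance=0.0)
        stops = [stopper.update(e, v) for e, v in enumerate([1.0] + [0.9] * 10, start=1)]
        assert stops.index(True) + 1 == 7
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=5, tolerance=0.0)
        assert not any(stopper.update(e, 1.0 / e) for e in range(1, 30))

    def test_tolerance_treats_tiny_gains_as_unchanged(self):
        stopper = EarlyStopper(patience=3, tolerance=1e-2)
        trace = [1.0, 0.995, 0.992, 0.991]  # never improves on 1.0 by > 0.01
        stops = [stopper.update(e, v) for e, v in enumerate(trace, start=1)]
        assert stops == [False, False, False, True]

    def test_train_model_injected_trace_stops_at_epoch_7(self, rng):
        cfg = TrainConfig(patience_epochs=5, patience_tolerance=0.0, max_epochs=30, seed=0)
        pred = build_segnet(tiny_cfg(), seed=0)
        trace = {1: 1.0}
        _, history = train_model(
            pred, _toy_dataset(rng), _toy_dataset(rng), cfg,
            val_loss_fn=lambda e: 1.0 if e == 1 else 0.9,
        )
        assert len(history) == 7

    def test_train_model_runs_to_max_epochs_when_improving(self, rng):
        cfg = TrainConfig(patience_epochs=5, patience_tolerance=0.0, max_epochs=4, seed=0)
        pred = build_segnet(tiny_cfg(), seed=0)
        _, history = train_model(
            pred, _toy_dataset(rng), _toy_dataset(rng), cfg, val_loss_fn=lambda e: 1.0 / e
        )
        assert len(history) == 4


class TestTrainModel:
    def test_empty_dataset_rejected(self, rng):
        pred = build_segnet(tiny_cfg(), 0)
        with pytest.raises(ValueError):
            train_model(pred, [], _toy_dataset(rng), TrainConfig(max_epochs=1))

    def test_same_seed_reproduces_history(self, rng):
        data = _toy_dataset(rng)
        val = _toy_dataset(rng)
        cfg = TrainConfig(max_epochs=3, seed=11)
        _, h1 = train_model(build_segnet(tiny_cfg(), 4), data, val, cfg)
        _, h2 = train_model(build_segnet(tiny_cfg(), 4), data, val, cfg)
        assert h1 == h2

    def test_loss_decreases_when_overfitting_one_sample(self, rng):
        data = _toy_dataset(rng, n=1)
        cfg = TrainConfig(max_epochs=8, seed=0)
        _, history = train_model(build_segnet(tiny_cfg(base_channels=3), 0), data, data, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]


class _ConstantPredictor:
    def __init__(self, value=0.3):
        self.value = value

    def predict(self, patch, context=None):
        return {"mask": np.full((1,) + patch.shape[1:], self.value, dtype=np.float32)}


class TestPredictPatchwise:
    def test_constant_predictor_is_tiling_invariant(self, rng):
        v = Volume(rng.random((12, 12, 12)).astype(np.float32), spacing=(1,) * 3)
        out = predict_patchwise(_ConstantPredictor(), v, (8, 8, 8), overlap_fraction=0.5)
        np.testing.assert_allclose(out["mask"], 0.3, atol=1e-6)

    def test_single_window_equals_direct_call(self, rng):
        cfg = tiny_cfg()
        pred = build_segnet(cfg, 0)
        v = Volume(rng.random((8, 8, 8)).astype(np.float32), spacing=(1,) * 3)
        tiled = predict_patchwise(pred, v, (8, 8, 8))
        direct = pred.predict(v.voxels[None].astype(np.float32))
        np.testing.assert_allclose(tiled["mask"], direct["mask"], atol=1e-6)

    def test_predictor_failure_reported_with_window(self, rng):
        class Boom:
            def predict(self, patch, context=None):
                raise RuntimeError("boom")

        v = Volume(rng.random((8, 8, 8)).astype(np.float32), spacing=(1,) * 3)
        with pytest.raises(RuntimeError, match="window"):
            predict_patchwise(Boom(), v, (8, 8, 8))


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        cfg = tiny_cfg(heads=(HeadSpec("offset", 3, "linear"), HeadSpec("mask", 1, "sigmoid")),
                       n_classes=32)
        pred = build_segnet(cfg, seed=3)
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        before = pred.predict(x)
        save_checkpoint(pred, tmp_path / "m.npz")
        after = load_checkpoint(tmp_path / "m.npz").predict(x)
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
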