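"""Network construction, loss identities, training, prediction."""

import numpy as np
import pytest

from octreveng import segnet
from octreveng._nn import maxpool2x2, unpool2x2
from octreveng.segnet import (UNetConfig, binarize, build_unet, dice_bce_loss,
                              load_model, predict, save_model, train,
                              _loss_and_logit_grad)


def tiny_cfg(**kw):
    base = dict(depth=2, base_channels=4, in_shape=(32, 32),
                learning_rate=1e-3, epochs=2, batch_size=2, seed=5)
    base.update(kw)
    return UNetConfig(**base)


class TestBuildUnet:
    def test_output_shape_and_softmax(self, rng):
        cfg = tiny_cfg(depth=2, base_channels=8, in_shape=(64, 64))
        model = build_unet(cfg)
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        logits = model.forward(x)
        assert logits.shape == (1, 2, 64, 64)
        probs = segnet.softmax2(logits)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_same_seed_same_weights(self):
        a = build_unet(tiny_cfg(seed=3))
        b = build_unet(tiny_cfg(seed=3))
        for (va, _), (vb, _) in zip(a.params, b.params):
            assert np.array_equal(va, vb)
        c = build_unet(tiny_cfg(seed=4))
        assert any(not np.array_equal(va, vc)
                   for (va, _), (vc, _) in zip(a.params, c.params))

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            tiny_cfg(depth=3, in_shape=(36, 36))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            tiny_cfg(kernel_size=4)


class TestDiceBceLoss:
    def test_perfect_binary_match_is_zero(self):
        truth = np.zeros((8, 8))
        truth[2:4, 2:6] = 1
        lv = dice_bce_loss(truth.copy(), truth)
        assert abs(lv.dice_term) < 1e-12
        assert lv.bce_term < 1e-5      # clamp leaves ~1e-7 per pixel
        assert lv.total == lv.dice_term + lv.bce_term

    def test_empty_truth_empty_pred_dice_zero(self):
        lv = dice_bce_loss(np.zeros((6, 6)), np.zeros((6, 6)))
        assert lv.dice_term == 0.0     # smoothing: 1 - 1/1

    def test_hand_computed_example(self):
        """2 positives of 4 pixels, uniform prediction 0.9: values forced by
        the printed formula with soft cardinalities."""
        pred = np.full((2, 2), 0.9)
        truth = np.array([[1.0, 1.0], [0.0, 0.0]])
        lv = dice_bce_loss(pred, truth)
        expected_dice = 1 - (2 * 1.8 + 1) / (3.6 + 2 + 1)
        expected_bce = -(2 * np.log(0.9) + 2 * np.log(0.1)) / 4
        assert np.isclose(lv.dice_term, expected_dice, atol=1e-12)
        assert np.isclose(lv.bce_term, expected_bce, atol=1e-9)
        assert np.isclose(lv.total, expected_dice + expected_bce, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_bce_loss(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_permutation_equivariance(self, rng):
        pred = rng.random((8, 8))
        truth = (rng.random((8, 8)) > 0.7).astype(float)
        perm = rng.permutation(64)
        lv = dice_bce_loss(pred, truth)
        lp = dice_bce_loss(pred.ravel()[perm].reshape(8, 8),
                           truth.ravel()[perm].reshape(8, 8))
        assert np.isclose(lv.total, lp.total, atol=1e-12)

    def test_dice_monotone_in_true_positive_probability(self, rng):
        pred = rng.random((8, 8))
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        ti, tj = np.argwhere(truth > 0)[0]
        base = dice_bce_loss(pred, truth).dice_term
        for bump in (0.01, 0.05, min(0.2, 1 - pred[ti, tj])):
            up = pred.copy()
            up[ti, tj] = min(1.0, up[ti, tj] + bump)
            assert dice_bce_loss(up, truth).dice_term <= base + 1e-12


class TestGradient:
    def test_backprop_matches_finite_differences(self, rng):
        """Full-network gradient check at float64 on a 4x4 case.

        Biases are randomized so the check happens at a generic point of
        the piecewise-smooth loss (zero biases put pre-activations exactly
        on ReLU kinks where one-sided derivatives differ).
        """
        cfg = tiny_cfg(depth=1, base_channels=2, in_shape=(4, 4), seed=2)
        model = build_unet(cfg, dtype=np.float64)
        for val, _ in model.params:
            val += rng.normal(scale=0.05, size=val.shape)
        x = rng.random((1, 1, 4, 4))
        truth = (rng.random((1, 4, 4)) > 0.5).astype(float)
        logits = model.forward(x, keep=True)
        _, dlogits, _, _ = _loss_and_logit_grad(logits, truth)
        model.backward(dlogits)
        worst = 0.0
        for val, grad in model.params:
            it = np.nditer(val, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                eps, old = 1e-6, val[idx]
                val[idx] = old + eps
                lp = _loss_and_logit_grad(model.forward(x), truth)[0]
                val[idx] = old - eps
                lm = _loss_and_logit_grad(model.forward(x), truth)[0]
                val[idx] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(grad[idx]), 1e-4)
                worst = max(worst, abs(num - grad[idx]) / denom)
                it.iternext()
        assert worst < 1e-4


class TestTrain:
    def test_history_shape_and_finiteness(self, rng):
        cfg = tiny_cfg(epochs=1)
        model = build_unet(cfg)
        x = rng.random((32, 32), dtype=np.float32)
        y = (rng.random((32, 32)) > 0.8)
        hist = train(model, [(x, y)], cfg)
        assert len(hist) == 1
        assert np.isfinite(hist[0]["mean_loss"])
        assert set(hist[0]) == {"epoch", "mean_loss", "dice_term", "bce_term"}

    def test_empty_dataset_rejected(self):
        cfg = tiny_cfg()
        with pytest.raises(ValueError, match="empty"):
            train(build_unet(cfg), [], cfg)

    def test_same_seed_reproducible(self, rng):
        cfg = tiny_cfg(epochs=3)
        samples = [(rng.random((32, 32), dtype=np.float32),
                    rng.random((32, 32)) > 0.8) for _ in range(4)]
        h1 = train(build_unet(cfg), samples, cfg)
        h2 = train(build_unet(cfg), samples, cfg)
        assert h1 == h2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_memorizes_four_bscans(self, seed):
        """Small-capacity memorization: 50 epochs on 4 structured B-scans
        drives the training loss below 0.1."""
        r = np.random.default_rng(seed)
        samples = []
        for _ in range(4):
            x = (r.random((64, 64)) * 0.2).astype(np.float32)
            c, w = int(r.integers(14, 50)), int(r.integers(5, 10))
            x[20:30, c - w:c + w] += 0.7
            mask = np.zeros((64, 64), dtype=bool)
            mask[:, c - w:c + w] = True
            samples.append((x, mask))
        cfg = UNetConfig(depth=3, base_channels=16, in_shape=(64, 64),
                         learning_rate=3e-3, epochs=50, batch_size=2,
                         seed=seed)
        model = build_unet(cfg)
        hist = train(model, samples, cfg)
        assert hist[-1]["mean_loss"] < 0.1


class TestPredictAndBinarize:
    def test_predict_deterministic_and_valid(self, rng):
        cfg = tiny_cfg()
        model = build_unet(cfg)
        b = rng.random((32, 32))
        p1, p2 = predict(model, b), predict(model, b)
        assert np.array_equal(p1, p2)
        assert p1.min() >= 0 and p1.max() <= 1

    def test_predict_shape_mismatch(self, rng):
        model = build_unet(tiny_cfg())
        with pytest.raises(ValueError, match="shape"):
            predict(model, rng.random((16, 16)))

    def test_binarize_is_strictly_greater(self):
        p = np.array([[0.5, 0.500001], [0.0, 1.0]])
        out = binarize(p, 0.5)
        assert not out[0, 0]      # exactly at threshold -> negative
        assert out[0, 1]
        assert not out[1, 0] and out[1, 1]
        assert not binarize(np.zeros((4, 4))).any()

    def test_binarize_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=0.0)


class TestCheckpoint:
    def test_round_trip(self, rng, tmp_path):
        cfg = tiny_cfg()
        model = build_unet(cfg)
        b = rng.random((32, 32))
        save_model(model, tmp_path / "m.npz")
        again = load_model(tmp_path / "m.npz")
        assert again.cfg == cfg
        assert np.array_equal(predict(model, b), predict(again, b))

    def test_missing_checkpoint(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="checkpoint"):
            load_model(tmp_path / "nope.npz")


def test_pool_unpool_contract(rng):
    x = rng.random((2, 3, 8, 8)).astype(np.float32)
    pooled, sw = maxpool2x2(x)
    up = unpool2x2(pooled, sw)
    # at most one nonzero per 2x2 window, carrying that window's max
    win = up.reshape(2, 3, 4, 2, 4, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(2, 3, 4, 4, 4)
    assert (np.sort(win, axis=-1)[..., :3] == 0).all()
    assert np.array_equal(win.max(axis=-1), pooled)
    p2, _ = maxpool2x2(up)
    assert np.array_equal(p2, pooled)
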